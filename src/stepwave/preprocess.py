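"""Front-end conditioning of the AP acceleration.

The detection pipeline runs detrend -> low-pass -> cumulative
integration before any wavelet stage.  Filtering is zero-phase
(forward-backward second-order Butterworth), so event times are not
lag-shifted; the effective magnitude response is the squared one-pass
response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.integrate
import scipy.signal

from .errors import ParameterError


@dataclass
class Series1D:
    """A uniformly sampled scalar series."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("Series1D values must be one-dimensional")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("Series1D values must be finite")

    @property
    def n(self) -> int:
        return len(self.values)

    def time(self) -> np.ndarray:
        return np.arange(self.n) / self.fs


def linear_detrend(x: Series1D) -> Series1D:
    """Remove the least-squares straight line from ``x``."""
    if x.n < 2:
        raise ParameterError("linear_detrend needs at least 2 samples")
    return Series1D(scipy.signal.detrend(x.values, type="linear"), x.fs)


def lowpass(x: Series1D, cutoff_hz: float, order: int = 2) -> Series1D:
    """Zero-phase Butterworth low-pass filter.

    ``cutoff_hz`` must lie below Nyquist.  Reflective padding of at
    least three filter time constants suppresses edge transients.
    """
    if not 0 < cutoff_hz < x.fs / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={x.fs / 2} Hz)"
        )
    sos = scipy.signal.butter(order, cutoff_hz, btype="low", fs=x.fs, output="sos")
    padlen = min(x.n - 1, max(int(np.ceil(3 * x.fs / cutoff_hz)), 3 * order))
    y = scipy.signal.sosfiltfilt(sos, x.values, padtype="even", padlen=padlen)
    return Series1D(y, x.fs)


def integrate_cumulative(x: Series1D) -> Series1D:
    """Cumulative trapezoidal integral; the first output sample is 0."""
    y = scipy.integrate.cumulative_trapezoid(x.values, dx=1.0 / x.fs, initial=0.0)
    return Series1D(y, x.fs)
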