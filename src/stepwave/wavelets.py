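"""Single-scale CWT differentiation and scale selection.

The detector needs exactly one wavelet transform per stage, at one
scale chosen from the dominant step frequency:

    a = Fc / (Fa * delta)

where ``Fc`` is the wavelet's centre frequency (in cycles per unit of
the wavelet's natural coordinate), ``Fa`` the dominant (pseudo-)
frequency in Hz and ``delta`` the sampling period in seconds.

Three wavelets are supported.  ``GAUS1``/``GAUS2`` are the L2-normalised
first/second derivatives of a Gaussian; correlating a signal with them
yields a smoothed first/second derivative with the sign conventions

    cwt(x, GAUS1, a) ~ -(smoothed x)'          (odd kernel)
    cwt(x, GAUS2, a) ~ +(smoothed x)''         (even kernel)

``DB2`` is the Daubechies 2-vanishing-moment wavelet, built by the
cascade refinement of its reconstruction filters.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .errors import NoDominantFrequencyError, ParameterError
from .preprocess import Series1D


class WaveletKind(str, enum.Enum):
    GAUS1 = "gaus1"
    GAUS2 = "gaus2"
    DB2 = "db2"


#: Standard centre-frequency constants (cycles per unit wavelet coordinate).
CENTER_FREQUENCY = {
    WaveletKind.GAUS1: 0.2,
    WaveletKind.GAUS2: 0.3,
    WaveletKind.DB2: 2.0 / 3.0,
}

# db2 reconstruction filters (orthonormal, sum(lo) = sqrt(2))
_SQRT3 = np.sqrt(3.0)
_DB2_REC_LO = np.array([1.0 + _SQRT3, 3.0 + _SQRT3, 3.0 - _SQRT3, 1.0 - _SQRT3]) / (4.0 * np.sqrt(2.0))
_DB2_REC_HI = np.array([_DB2_REC_LO[3], -_DB2_REC_LO[2], _DB2_REC_LO[1], -_DB2_REC_LO[0]])


@dataclass(frozen=True)
class WaveletScaleParams:
    """Scale bound to the quantities it was derived from."""

    a: float
    Fc: float
    Fa: float
    delta: float

    def __post_init__(self) -> None:
        for name in ("a", "Fc", "Fa", "delta"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if abs(self.a - self.Fc / (self.Fa * self.delta)) > 1e-9 * self.a:
            raise ParameterError("inconsistent scale: a != Fc / (Fa * delta)")


def scale_from_frequency(Fc: float, Fa: float, delta: float) -> float:
    """Scale (in samples) whose pseudo-frequency equals ``Fa``."""
    if Fc <= 0 or Fa <= 0 or delta <= 0:
        raise ParameterError("Fc, Fa and delta must all be strictly positive")
    return Fc / (Fa * delta)


def frequency_from_scale(Fc: float, a: float, delta: float) -> float:
    """Pseudo-frequency (Hz) of scale ``a`` — inverse of scale_from_frequency."""
    if Fc <= 0 or a <= 0 or delta <= 0:
        raise ParameterError("Fc, a and delta must all be strictly positive")
    return Fc / (a * delta)


@functools.lru_cache(maxsize=None)
def _wavefun(kind: WaveletKind, level: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Return (x, psi) samples of the mother wavelet.

    Gaussian-derivative wavelets are evaluated in closed form on
    [-5, 5].  db2 is built by ``level`` cascade iterations; its grid is
    re-centred on the energy centroid of psi so that correlation output
    is time-aligned with the feature driving it.
    """
    if kind in (WaveletKind.GAUS1, WaveletKind.GAUS2):
        x = np.linspace(-5.0, 5.0, 2 ** level)
        g = np.exp(-(x ** 2))
        if kind == WaveletKind.GAUS1:
            psi = -2.0 * x * g
        else:
            psi = (4.0 * x ** 2 - 2.0) * g
        dx = x[1] - x[0]
        psi = psi / np.sqrt(np.sum(psi ** 2) * dx)
        return x, psi
    # db2 cascade: reconstruct a single unit detail coefficient
    w = _DB2_REC_HI.copy()
    for _ in range(level - 1):
        up = np.zeros(2 * len(w))
        up[::2] = w
        w = np.convolve(up, _DB2_REC_LO)
    x = np.linspace(0.0, 3.0, len(w))
    dx = x[1] - x[0]
    w = w / np.sqrt(np.sum(w ** 2) * dx)
    centroid = float(np.sum(x * w ** 2) * dx)  # psi is unit-norm
    return x - centroid, w


def center_frequency(kind: WaveletKind, *, numeric: bool = False) -> float:
    """Centre frequency constant (or its numeric FFT-peak estimate)."""
    if not numeric:
        return CENTER_FREQUENCY[kind]
    # classic coarse-FFT recipe that the published constants come from:
    # peak bin of |FFT(psi)| over the wavelet's own support length
    x, psi = _wavefun(kind, 8)
    domain = x[-1] - x[0]
    index = int(np.argmax(np.abs(np.fft.fft(psi)[1:]))) + 2
    if index > len(psi) / 2:
        index = len(psi) - index + 2
    return float((index - 1) / domain)


def dominant_frequency(x: Series1D, band: tuple[float, float] = (0.5, 3.0),
                       *, peak_factor: float = 3.0) -> float:
    """Dominant frequency of ``x`` within ``band`` via a Welch periodogram.

    Raises :class:`NoDominantFrequencyError` when the in-band maximum
    does not exceed ``peak_factor`` times the in-band median power
    (flat / white spectrum).
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ParameterError("band must satisfy 0 < low < high")
    if x.n / x.fs < 4.0 / lo:
        raise ParameterError(
            f"series too short for band low {lo} Hz: need >= {4.0 / lo:.1f} s"
        )
    nperseg = min(x.n, int(round(10.0 * x.fs)))
    freqs, psd = scipy.signal.welch(x.values, fs=x.fs, nperseg=nperseg,
                                    noverlap=nperseg // 2)
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ParameterError("no spectral bins inside band")
    fb, pb = freqs[mask], psd[mask]
    k = int(np.argmax(pb))
    if pb[k] <= 0 or pb[k] < peak_factor * np.median(pb):
        raise NoDominantFrequencyError(
            f"no dominant frequency in [{lo}, {hi}] Hz "
            f"(peak/median = {pb[k] / max(np.median(pb), 1e-300):.2f})"
        )
    # parabolic refinement on log power for off-bin tones
    if 0 < k < len(pb) - 1 and pb[k - 1] > 0 and pb[k + 1] > 0:
        y0, y1, y2 = np.log(pb[k - 1]), np.log(pb[k]), np.log(pb[k + 1])
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            shift = 0.5 * (y0 - y2) / denom
            if abs(shift) <= 1:
                return float(fb[k] + shift * (fb[1] - fb[0]))
    return float(fb[k])


def cwt_single_scale(x: Series1D, kind: WaveletKind, a: float) -> Series1D:
    """Continuous wavelet coefficients of ``x`` at the single scale ``a``.

    The signal is extended symmetrically by ``2 a`` samples before the
    correlation and trimmed afterwards, so boundary extrema are not
    reported as events.  Output has the same length as the input.
    """
    if a < 1:
        raise ParameterError(f"scale a={a} must be >= 1 sample")
    if x.n < 10 * a:
        raise ParameterError(
            f"series of {x.n} samples too short for scale {a:.1f} (need >= {int(10 * a)})"
        )
    xg, psi = _wavefun(kind)
    m = np.arange(int(np.ceil(a * xg[0])), int(np.floor(a * xg[-1])) + 1)
    kern = np.interp(m / a, xg, psi)
    kern = kern - kern.mean()  # keep the sampled kernel zero-mean
    i0 = int(np.searchsorted(m, 0))  # kernel index of wavelet coordinate 0

    pad = int(np.ceil(2 * a))
    xp = np.pad(x.values, pad, mode="symmetric")
    full = np.correlate(xp, kern, mode="full")
    # full[q] = sum_j xp[q - (len(kern)-1) + j] * kern[j]; align j = i0 with b
    start = len(kern) - 1 - i0
    c = full[start:start + len(xp)] / np.sqrt(a)
    return Series1D(c[pad:pad + x.n], x.fs)
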