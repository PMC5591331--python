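"""Synthetic lower-back IMU recordings with exact ground truth.

The AP waveform is a cadence-locked harmonic shape plus a decaying
heel-strike transient, Gaussian noise and an optional tremor tone — not
a biomechanical model.  The harmonic coefficients below are calibrated
once so that the band-limited waveform peak (the feature a smoothed
differentiator keys on) coincides with the ground-truth heel-strike
instant at phase zero; the calibration is a property of the waveform,
not of any particular detector run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .io import InertialRecording
from .turns import TurnInterval, check_non_overlapping

# frozen waveform shape: W(p) = cos(p+PHASE) + H2_AMP*cos(2(p+PHASE)+H2_PHASE)
_WAVE_H2_AMP = 0.45
_WAVE_H2_PHASE = 2.0
_WAVE_PHASE_CAL = -0.2764601535158897  # aligns band-limited peak with phase 0

_HS_TRANSIENT_FREQ_HZ = 8.0
_HS_TRANSIENT_TAU_S = 0.05
_HS_TRANSIENT_REL_AMP = 0.3

_GRAVITY = 9.80665
_GYRO_NOISE_SD_DPS = 1.0
_GYRO_BIAS_DPS = 0.4

#: steps shorten inside turns by this factor
_TURN_CADENCE_FACTOR = 1.15

# home-like session layout (s)
_BOUT_WALK_S = 25.0
_BOUT_IDLE_S = 8.0
_TURN_PAD_S = 2.5
_BOUT_TAPER_S = 0.3


@dataclass(frozen=True)
class GaitSimParams:
    """Generator parameters; defaults mimic preferred-speed treadmill gait."""

    duration: float = 120.0
    fs: float = 100.0
    cadence: float = 1.8
    step_time_cv: float = 0.03
    hs_impulse_amp: float = 1.5
    noise_sd: float = 0.15
    tremor_amp: float = 0.0
    tremor_freq: float = 5.0
    stance_fraction: float = 0.60
    turn_script: tuple[TurnInterval, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.cadence <= 3.0:
            raise ParameterError("cadence must lie in [0.5, 3] steps/s")
        if self.duration < 10.0:
            raise ParameterError("duration must be >= 10 s")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if not 0.55 <= self.stance_fraction <= 0.70:
            raise ParameterError("stance_fraction must lie in [0.55, 0.70]")
        if self.tremor_amp > 0 and not 4.0 <= self.tremor_freq <= 6.0:
            raise ParameterError("tremor_freq must lie in [4, 6] Hz")
        check_non_overlapping(list(self.turn_script))
        for t in self.turn_script:
            if t.start < 0 or t.end > self.duration:
                raise ParameterError("scripted turn outside the session span")


@dataclass
class SyntheticTruth:
    """Ground truth bound to a simulated recording."""

    hs_times: np.ndarray
    to_times: np.ndarray
    turn_intervals: list[TurnInterval] = field(default_factory=list)
    params: GaitSimParams | None = None

    def __post_init__(self) -> None:
        self.hs_times = np.asarray(self.hs_times, dtype=float)
        self.to_times = np.asarray(self.to_times, dtype=float)


def _waveform(phase: np.ndarray) -> np.ndarray:
    p = phase + _WAVE_PHASE_CAL
    return np.cos(p) + _WAVE_H2_AMP * np.cos(2.0 * p + _WAVE_H2_PHASE)


def _step_intervals(rng: np.random.Generator, n: int, cadence: float, cv: float) -> np.ndarray:
    """Log-normal step intervals with mean 1/cadence and the given CV."""
    mean = 1.0 / cadence
    if cv <= 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _to_times_from_hs(hs: np.ndarray, stance_fraction: float) -> np.ndarray:
    """TO of the contralateral foot between consecutive HS.

    A stance of ``f`` stride (stride = two steps) puts each TO at
    ``(2 f - 1)`` step intervals after the preceding HS.
    """
    if len(hs) < 2:
        return np.empty(0)
    intervals = np.diff(hs)
    return hs[:-1] + (2.0 * stance_fraction - 1.0) * intervals


def _phase_from_hs(t: np.ndarray, hs: np.ndarray, cadence: float) -> np.ndarray:
    """Piecewise-linear phase with 2*pi*k at the k-th heel strike."""
    knots_t = np.concatenate(([hs[0] - 1.0 / cadence], hs, [hs[-1] + 1.0 / cadence]))
    knots_p = 2.0 * np.pi * np.arange(-1, len(hs) + 1)
    return np.interp(t, knots_t, knots_p)


def _hs_transients(t: np.ndarray, hs: np.ndarray, fs: float, amp: float) -> np.ndarray:
    out = np.zeros_like(t)
    span = int(round(6 * _HS_TRANSIENT_TAU_S * fs))
    for th in hs:
        i0 = int(np.ceil(th * fs))
        i1 = min(i0 + span, len(t))
        if i0 >= len(t):
            continue
        dt = t[i0:i1] - th
        out[i0:i1] += amp * np.exp(-dt / _HS_TRANSIENT_TAU_S) * np.sin(
            2.0 * np.pi * _HS_TRANSIENT_FREQ_HZ * dt)
    return out


def _assemble(params: GaitSimParams, rng: np.random.Generator, t: np.ndarray,
              ap_gait: np.ndarray, yaw_rate: np.ndarray) -> InertialRecording:
    n = len(t)
    noise = rng.normal(0.0, params.noise_sd, size=(n, 3))
    ap = ap_gait + noise[:, 0]
    if params.tremor_amp > 0:
        ap = ap + params.tremor_amp * np.sin(
            2.0 * np.pi * params.tremor_freq * t + rng.uniform(0, 2 * np.pi))
    ml = 0.4 * noise[:, 1]
    vert = _GRAVITY + 0.5 * noise[:, 2]
    gyro = rng.normal(0.0, _GYRO_NOISE_SD_DPS, size=(n, 3))
    gyro[:, 2] += yaw_rate + _GYRO_BIAS_DPS
    accel = np.column_stack([ap, ml, vert])
    return InertialRecording(fs=params.fs, accel=accel, gyro=gyro)


def simulate_treadmill(params: GaitSimParams | None = None) -> tuple[InertialRecording, SyntheticTruth]:
    """Continuous straight walking at the commanded cadence."""
    params = params or GaitSimParams()
    if params.turn_script:
        raise ParameterError("treadmill simulation takes an empty turn script")
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.fs))
    t = np.arange(n) / params.fs

    n_steps = int(np.ceil(params.duration * params.cadence)) + 4
    intervals = _step_intervals(rng, n_steps, params.cadence, params.step_time_cv)
    hs = 0.6 + np.cumsum(np.concatenate(([0.0], intervals)))
    hs = hs[hs <= params.duration - 0.4]
    if len(hs) < 2:
        raise ParameterError("duration too short for the commanded cadence")

    phase = _phase_from_hs(t, hs, params.cadence)
    ap = params.hs_impulse_amp * _waveform(phase)
    ap += _hs_transients(t, hs, params.fs, _HS_TRANSIENT_REL_AMP * params.hs_impulse_amp)
    rec = _assemble(params, rng, t, ap, np.zeros(n))
    to = _to_times_from_hs(hs, params.stance_fraction)
    return rec, SyntheticTruth(hs, to, [], params)


def _walk_bouts(params: GaitSimParams) -> list[tuple[float, float]]:
    """Walking coverage: a fixed walk/idle pattern, extended to cover turns."""
    spans: list[tuple[float, float]] = []
    pos = 1.0
    while pos < params.duration - 1.0:
        end = min(pos + _BOUT_WALK_S, params.duration - 1.0)
        spans.append((pos, end))
        pos = end + _BOUT_IDLE_S
    for turn in params.turn_script:
        spans.append((max(turn.start - _TURN_PAD_S, 0.0),
                      min(turn.end + _TURN_PAD_S, params.duration)))
    spans.sort()
    merged = [spans[0]]
    for s, e in spans[1:]:
        if s <= merged[-1][1] + 1e-9:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _inside_turn(time: float, turns: tuple[TurnInterval, ...]) -> bool:
    return any(t.contains(time) for t in turns)


def simulate_homelike(params: GaitSimParams | None = None) -> tuple[InertialRecording, SyntheticTruth]:
    """Walking bouts with scripted turns and idle gaps.

    The yaw-rate channel realises the turn script with raised-cosine
    rate profiles; steps inside turns are shortened by a fixed factor.
    """
    params = params or GaitSimParams(fs=128.0)
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.fs))
    t = np.arange(n) / params.fs
    ap = np.zeros(n)
    hs_all: list[float] = []
    to_all: list[float] = []

    for b0, b1 in _walk_bouts(params):
        if b1 - b0 < 2.0:
            continue
        hs = []
        pos = b0 + 0.3
        while pos < b1 - 0.3:
            hs.append(pos)
            step = float(_step_intervals(rng, 1, params.cadence, params.step_time_cv)[0])
            if _inside_turn(pos, params.turn_script):
                step /= _TURN_CADENCE_FACTOR
            pos += step
        if len(hs) < 2:
            continue
        hs_arr = np.array(hs)
        i0, i1 = int(np.ceil(b0 * params.fs)), min(int(np.floor(b1 * params.fs)), n)
        phase = _phase_from_hs(t[i0:i1], hs_arr, params.cadence)
        wave = params.hs_impulse_amp * _waveform(phase)
        # taper the bout edges so start/stop transients stay smooth
        edge = np.minimum((t[i0:i1] - b0) / _BOUT_TAPER_S, (b1 - t[i0:i1]) / _BOUT_TAPER_S)
        wave *= np.clip(edge, 0.0, 1.0)
        ap[i0:i1] += wave
        hs_all.extend(hs_arr)
        to_all.extend(_to_times_from_hs(hs_arr, params.stance_fraction))

    ap += _hs_transients(t, np.array(hs_all), params.fs,
                         _HS_TRANSIENT_REL_AMP * params.hs_impulse_amp)

    yaw_rate = np.zeros(n)
    for turn in params.turn_script:
        i0 = int(np.ceil(turn.start * params.fs))
        i1 = min(int(np.floor(turn.end * params.fs)) + 1, n)
        dt = t[i0:i1] - turn.start
        dur = turn.duration
        yaw_rate[i0:i1] += (turn.yaw_excursion / dur) * (1.0 - np.cos(2.0 * np.pi * dt / dur))

    rec = _assemble(params, rng, t, ap, yaw_rate)
    truth = SyntheticTruth(np.sort(np.array(hs_all)), np.sort(np.array(to_all)),
                           list(params.turn_script), params)
    return rec, truth
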