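"""Turn detection from the vertical (yaw) angular velocity.

A turn is an excursion of the yaw angle larger than 90 degrees that
lasts between 0.5 and 10 s.  Candidate episodes are maximal runs of
consistent-sign smoothed yaw rate above 15 deg/s; the excursion is the
angle change between the run endpoints.  Episodes failing the magnitude
or duration window are assigned wholly to the non-turning context.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.integrate

from .errors import DataError, FormatError, ParameterError
from .io import PipelineParams
from .preprocess import Series1D, lowpass

#: Yaw-rate magnitude bounding a candidate turn episode (deg/s).
RATE_THRESHOLD_DPS = 15.0
#: After a run is found its endpoints are extended outward while the
#: smoothed rate keeps the run's sign above this floor, recovering the
#: slow tails of the excursion (hysteresis bounding).
RATE_FLOOR_DPS = 1.0
#: Same-direction episodes closer than this are merged (s).
MERGE_GAP_S = 0.2
#: Rate-smoothing cutoff used only for episode bounding (Hz).
RATE_SMOOTH_HZ = 1.5
#: Gyro bias is estimated (as the median rate) only on recordings at
#: least this long; shorter series are integrated as-is.
BIAS_MIN_DURATION_S = 20.0


@dataclass(frozen=True)
class TurnInterval:
    """A detected turn: [start, end] seconds, signed yaw excursion in degrees."""

    start: float
    end: float
    yaw_excursion: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ParameterError("turn interval must have end > start")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


def yaw_angle(gyro_vertical: Series1D, *, correct_bias: bool | None = None) -> Series1D:
    """Cumulative yaw angle (degrees) from the vertical angular velocity.

    Bias correction subtracts the median rate, which is robust because
    turning occupies a small fraction of a long recording; a high-pass
    filter is deliberately not used since it bleeds the step-like angle
    profile of a genuine turn back toward zero within a few seconds.
    By default the correction is applied only to recordings longer than
    ``BIAS_MIN_DURATION_S``.
    """
    rate = gyro_vertical.values
    if correct_bias is None:
        correct_bias = gyro_vertical.n / gyro_vertical.fs >= BIAS_MIN_DURATION_S
    if correct_bias:
        rate = rate - np.median(rate)
    ang = scipy.integrate.cumulative_trapezoid(rate, dx=1.0 / gyro_vertical.fs,
                                               initial=0.0)
    return Series1D(ang, gyro_vertical.fs)


def _candidate_runs(rate: np.ndarray, fs: float) -> list[tuple[int, int]]:
    """Maximal consistent-sign runs with |rate| above threshold."""
    sign = np.where(rate > RATE_THRESHOLD_DPS, 1,
                    np.where(rate < -RATE_THRESHOLD_DPS, -1, 0))
    runs: list[tuple[int, int, int]] = []  # (start, end, sign)
    i = 0
    n = len(sign)
    while i < n:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j < n and sign[j] == sign[i]:
            j += 1
        runs.append((i, j, int(sign[i])))
        i = j
    # merge same-direction runs separated by a short sub-threshold gap
    merged: list[tuple[int, int, int]] = []
    max_gap = int(round(MERGE_GAP_S * fs))
    for run in runs:
        if merged and run[2] == merged[-1][2] and run[0] - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], run[1], run[2])
        else:
            merged.append(run)
    return [(s, e) for s, e, _ in merged]


def detect_turns(angle: Series1D, params: PipelineParams | None = None) -> list[TurnInterval]:
    """Detect turns in a yaw-angle series (degrees).

    Returns accepted turns only (|excursion| > ``turn_min_angle_deg``,
    duration within [``turn_min_dur_s``, ``turn_max_dur_s``]), ordered
    and non-overlapping.
    """
    params = params or PipelineParams()
    rate = np.gradient(angle.values) * angle.fs
    if angle.fs > 2.5 * RATE_SMOOTH_HZ:
        rate = lowpass(Series1D(rate, angle.fs), RATE_SMOOTH_HZ).values
    out: list[TurnInterval] = []
    last_end = -1
    for s, e in _candidate_runs(rate, angle.fs):
        sgn = 1.0 if rate[s] > 0 else -1.0
        while s - 1 > last_end and sgn * rate[s - 1] > RATE_FLOOR_DPS:
            s -= 1
        while e < angle.n and sgn * rate[min(e, angle.n - 1)] > RATE_FLOOR_DPS:
            e += 1
        last_end = e
        e_idx = min(e, angle.n - 1)
        dur = (e_idx - s) / angle.fs
        exc = float(angle.values[e_idx] - angle.values[s])
        if abs(exc) > params.turn_min_angle_deg and \
                params.turn_min_dur_s <= dur <= params.turn_max_dur_s:
            out.append(TurnInterval(s / angle.fs, e_idx / angle.fs, exc))
    return out


def check_non_overlapping(turns: list[TurnInterval]) -> list[TurnInterval]:
    """Sort turns by start and raise on any overlap."""
    turns = sorted(turns, key=lambda t: t.start)
    for a, b in zip(turns, turns[1:]):
        if b.start < a.end:
            raise ParameterError(
                f"turn intervals overlap: [{a.start}, {a.end}] and [{b.start}, {b.end}]"
            )
    return turns


def write_turns(turns: list[TurnInterval], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {"turns": [
            {"start_s": t.start, "end_s": t.end, "yaw_excursion_deg": t.yaw_excursion}
            for t in turns
        ]}
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    lines = ["start_s,end_s,yaw_excursion_deg"]
    for t in turns:
        lines.append(f"{t.start:.6f},{t.end:.6f},{t.yaw_excursion:.3f}")
    path.write_text("\n".join(lines) + "\n")


def read_turns(path: str | Path) -> list[TurnInterval]:
    path = Path(path)
    turns: list[TurnInterval] = []
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        for row in data.get("turns", []):
            turns.append(TurnInterval(float(row["start_s"]), float(row["end_s"]),
                                      float(row["yaw_excursion_deg"])))
        return check_non_overlapping(turns)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].lower().startswith("start_s"):
        raise FormatError(f"{path}: expected turn CSV with start_s,end_s header")
    for ln in lines[1:]:
        parts = ln.split(",")
        try:
            turns.append(TurnInterval(float(parts[0]), float(parts[1]), float(parts[2])))
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: bad turn row {ln!r}") from exc
    return check_non_overlapping(turns)
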