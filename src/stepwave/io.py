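"""Reading and writing IMU recordings, gait event lists and parameters.

Recordings are delimited text (CSV/TSV) with one row per sample.  A
:class:`RecordingDialect` maps file columns onto the internal axis
convention (AP/ML/V accelerometer axes, AP/ML/YAW gyroscope axes) and
declares units; nothing about the mounting orientation is ever inferred
from the data.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError, ParameterError

G_TO_MS2 = 9.80665
RAD_TO_DEG = 180.0 / math.pi

ACCEL_AXES = ("ap", "ml", "v")
GYRO_AXES = ("ap", "ml", "yaw")


class EventType(str, enum.Enum):
    HS = "HS"
    TO = "TO"
    STEP = "STEP"


class EventContext(str, enum.Enum):
    TURNING = "TURNING"
    NON_TURNING = "NON_TURNING"
    UNLABELED = "UNLABELED"


@dataclass(frozen=True)
class GaitEvent:
    time: float
    type: EventType
    context: EventContext = EventContext.UNLABELED


@dataclass
class GaitEventList:
    """Time-ordered heel-strike / toe-off / step events.

    Times are seconds on the recording's time base.  Within each event
    type the times must be strictly increasing.
    """

    events: list[GaitEvent] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = list(self.events)
        self._check()

    def _check(self) -> None:
        last: dict[EventType, float] = {}
        prev = -np.inf
        for ev in self.events:
            if ev.time < prev:
                raise DataError(f"event list not time-ordered at t={ev.time:.6f}")
            prev = ev.time
            if ev.type in last and ev.time <= last[ev.type]:
                raise DataError(
                    f"event times not strictly increasing for type {ev.type.value} "
                    f"at t={ev.time:.6f}"
                )
            last[ev.type] = ev.time

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def times(self, type: EventType | None = None) -> np.ndarray:
        sel = self.events if type is None else [e for e in self.events if e.type == type]
        return np.array([e.time for e in sel], dtype=float)

    def of_type(self, type: EventType) -> "GaitEventList":
        return GaitEventList([e for e in self.events if e.type == type])

    def in_context(self, context: EventContext) -> "GaitEventList":
        return GaitEventList([e for e in self.events if e.context == context])


@dataclass
class InertialRecording:
    """Uniformly sampled tri-axial accelerometer + gyroscope series.

    ``accel`` is (n, 3) in m/s^2 ordered (AP, ML, V); ``gyro`` is (n, 3)
    in deg/s ordered (AP, ML, YAW).  ``segments`` lists contiguous index
    ranges; a NaN gap longer than two samples splits the recording and
    each segment is processed independently downstream.
    """

    fs: float
    accel: np.ndarray
    gyro: np.ndarray | None = None
    t0: float = 0.0
    segments: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ParameterError("accel must have shape (n, 3)")
        if self.gyro is not None:
            self.gyro = np.asarray(self.gyro, dtype=float)
            if self.gyro.shape != self.accel.shape:
                raise ParameterError("gyro must match accel shape")
            if np.isnan(self.gyro).any():
                raise DataError("NaN present in gyro after ingestion")
        if np.isnan(self.accel).any():
            raise DataError("NaN present in accel after ingestion")
        if self.segments is None:
            self.segments = [(0, self.n)]

    @property
    def n(self) -> int:
        return self.accel.shape[0]

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def ap(self) -> np.ndarray:
        return self.accel[:, 0]

    @property
    def yaw_rate(self) -> np.ndarray:
        if self.gyro is None:
            raise DataError("recording has no gyroscope channels")
        return self.gyro[:, 2]

    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


@dataclass
class PipelineParams:
    """Global pipeline constants with the published defaults."""

    lowpass_cutoff_hz: float = 10.0
    filter_order: int = 2
    peak_threshold_fraction: float = 0.40
    match_tolerance_s: float = 0.3
    turn_min_angle_deg: float = 90.0
    turn_min_dur_s: float = 0.5
    turn_max_dur_s: float = 10.0
    dominant_freq_band_hz: tuple[float, float] = (0.5, 3.0)

    def __post_init__(self) -> None:
        if not 0 < self.peak_threshold_fraction < 1:
            raise ParameterError("peak_threshold_fraction must be in (0, 1)")
        if not self.turn_min_dur_s < self.turn_max_dur_s:
            raise ParameterError("turn_min_dur_s must be < turn_max_dur_s")
        lo, hi = self.dominant_freq_band_hz
        if not 0 < lo < hi:
            raise ParameterError("dominant_freq_band_hz must satisfy 0 < low < high")
        self.dominant_freq_band_hz = (float(lo), float(hi))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineParams":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise FormatError(f"config {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dominant_freq_band_hz"] = list(self.dominant_freq_band_hz)
        return d


@dataclass
class RecordingDialect:
    """Column map + units for a delimited-text recording.

    ``accel_columns`` / ``gyro_columns`` name the file columns for the
    (AP, ML, V) and (AP, ML, YAW) axes.  Either a ``time_column`` or a
    declared ``fs`` is required; if both are given they must agree to 1%.
    """

    accel_columns: tuple[str, str, str] = ("acc_ap", "acc_ml", "acc_v")
    gyro_columns: tuple[str, str, str] | None = ("gyr_ap", "gyr_ml", "gyr_yaw")
    time_column: str | None = "time_s"
    time_unit: str = "s"  # "s" | "ms"
    accel_unit: str = "m/s^2"  # "m/s^2" | "g"
    gyro_unit: str = "deg/s"  # "deg/s" | "rad/s"
    fs: float | None = None
    delimiter: str = ","

    def __post_init__(self) -> None:
        if self.time_unit not in ("s", "ms"):
            raise ParameterError(f"unsupported time unit {self.time_unit!r}")
        if self.accel_unit not in ("m/s^2", "g"):
            raise ParameterError(f"unsupported accel unit {self.accel_unit!r}")
        if self.gyro_unit not in ("deg/s", "rad/s"):
            raise ParameterError(f"unsupported gyro unit {self.gyro_unit!r}")
        if self.time_column is None and self.fs is None:
            raise ParameterError("dialect needs a time column or a declared fs")


def _infer_fs(t: np.ndarray) -> float:
    dt = np.diff(t)
    if len(dt) == 0:
        raise DataError("cannot infer sampling rate from a single sample")
    if np.any(dt <= 0):
        raise DataError("time column is not strictly increasing")
    return 1.0 / float(np.median(dt))


def read_recording(path: str | Path, dialect: RecordingDialect | None = None) -> InertialRecording:
    """Read a delimited-text recording, validating and converting units.

    Rows containing NaN in any mapped channel are dropped; a contiguous
    dropped gap longer than 2 samples splits the recording into segments.
    """
    dialect = dialect or RecordingDialect()
    try:
        df = pd.read_csv(path, sep=dialect.delimiter)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    needed = list(dialect.accel_columns)
    if dialect.gyro_columns is not None:
        gyro_present = all(c in df.columns for c in dialect.gyro_columns)
    else:
        gyro_present = False
    if dialect.gyro_columns is not None and not gyro_present:
        # gyro is optional unless explicitly required by the caller
        pass
    missing = [c for c in needed if c not in df.columns]
    if dialect.time_column is not None and dialect.time_column not in df.columns:
        if dialect.fs is None:
            missing.append(dialect.time_column)
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    if dialect.time_column is not None and dialect.time_column in df.columns:
        t = df[dialect.time_column].to_numpy(dtype=float)
        if dialect.time_unit == "ms":
            t = t / 1000.0
        fs = _infer_fs(t) if len(t) > 1 else (dialect.fs or 0.0)
        if dialect.fs is not None and len(t) > 1:
            if abs(fs - dialect.fs) / dialect.fs > 0.01:
                raise DataError(
                    f"declared fs={dialect.fs} differs from inferred fs={fs:.3f} by >1%"
                )
            fs = dialect.fs
        t0 = float(t[0]) if len(t) else 0.0
    else:
        fs = float(dialect.fs)  # type: ignore[arg-type]
        t0 = 0.0
    if fs <= 0:
        raise DataError("sampling rate could not be determined")

    accel = df[list(dialect.accel_columns)].to_numpy(dtype=float)
    if dialect.accel_unit == "g":
        accel = accel * G_TO_MS2
    gyro = None
    if gyro_present:
        gyro = df[list(dialect.gyro_columns)].to_numpy(dtype=float)
        if dialect.gyro_unit == "rad/s":
            gyro = gyro * RAD_TO_DEG

    # NaN row policy: drop, and split on gaps longer than 2 samples.
    bad = np.isnan(accel).any(axis=1)
    if gyro is not None:
        bad |= np.isnan(gyro).any(axis=1)
    segments: list[tuple[int, int]] | None = None
    if bad.any():
        keep = ~bad
        gap_edges = []
        run = 0
        kept_index = np.cumsum(keep)  # position in compacted array
        for i, b in enumerate(bad):
            if b:
                run += 1
            else:
                if run > 2:
                    gap_edges.append(int(kept_index[i] - 1))
                run = 0
        accel = accel[keep]
        gyro = gyro[keep] if gyro is not None else None
        bounds = [0, *gap_edges, accel.shape[0]]
        segments = [
            (bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
            if bounds[i + 1] > bounds[i]
        ]
    return InertialRecording(fs=fs, accel=accel, gyro=gyro, t0=t0, segments=segments)


def write_recording(rec: InertialRecording, path: str | Path,
                    dialect: RecordingDialect | None = None) -> None:
    """Write a recording as CSV in the default internal dialect (SI units)."""
    dialect = dialect or RecordingDialect()
    cols: dict[str, np.ndarray] = {}
    if dialect.time_column:
        cols[dialect.time_column] = rec.time()
    for j, name in enumerate(dialect.accel_columns):
        cols[name] = rec.accel[:, j]
    if rec.gyro is not None and dialect.gyro_columns is not None:
        for j, name in enumerate(dialect.gyro_columns):
            cols[name] = rec.gyro[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.8g")


_EVENT_HEADER = "time_s,type,context"


def write_events(events: GaitEventList, path: str | Path) -> None:
    """Write events as CSV ``time_s,type,context`` (or JSON if path ends .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "events": [
                {"time_s": round(e.time, 6), "type": e.type.value, "context": e.context.value}
                for e in events
            ]
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    lines = [_EVENT_HEADER]
    for e in events:
        lines.append(f"{e.time:.6f},{e.type.value},{e.context.value}")
    path.write_text("\n".join(lines) + "\n")


def _parse_event(time_s: float, type_tok: str, context_tok: str | None) -> GaitEvent:
    try:
        etype = EventType(type_tok.strip().upper())
    except ValueError as exc:
        raise FormatError(f"unknown event type token {type_tok!r}") from exc
    if context_tok is None or context_tok.strip() == "":
        ctx = EventContext.UNLABELED
    else:
        try:
            ctx = EventContext(context_tok.strip().upper())
        except ValueError as exc:
            raise FormatError(f"unknown event context token {context_tok!r}") from exc
    return GaitEvent(float(time_s), etype, ctx)


def read_events(path: str | Path) -> GaitEventList:
    """Read an event list from CSV (``time_s,type[,context]``) or JSON."""
    path = Path(path)
    events: list[GaitEvent] = []
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        for row in data.get("events", []):
            events.append(_parse_event(row["time_s"], row["type"], row.get("context")))
        return GaitEventList(events)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty event file (expected a header row)")
    header = [h.strip().lower() for h in lines[0].split(",")]
    if "time_s" not in header or "type" not in header:
        raise FormatError(f"{path}: event header must contain time_s and type")
    it, ity = header.index("time_s"), header.index("type")
    ictx = header.index("context") if "context" in header else None
    for ln in lines[1:]:
        parts = ln.split(",")
        try:
            t = float(parts[it])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: bad event row {ln!r}") from exc
        ctx = parts[ictx] if ictx is not None and ictx < len(parts) else None
        events.append(_parse_event(t, parts[ity], ctx))
    return GaitEventList(events)
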