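"""Heel-strike / toe-off detection by single-scale CWT differentiation.

Treadmill pipeline (per contiguous segment):

    detrend -> low-pass 10 Hz -> integrate
        -> cwt(gaus1, a)  : local minima  -> HS
        -> cwt(gaus2, a') of that signal : local maxima -> TO

with the scale ``a`` chosen from the dominant spectral frequency of the
AP acceleration and every retained extremum exceeding 40% of the mean
candidate magnitude.  The home-like variant detects steps only, with a
gaus2 wavelet inside turning periods and a db2 wavelet outside.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal
import scipy.stats

from .errors import NoDominantFrequencyError, ParameterError
from .io import EventContext, EventType, GaitEvent, GaitEventList, InertialRecording, PipelineParams
from .preprocess import Series1D, integrate_cumulative, linear_detrend, lowpass
from .turns import TurnInterval, check_non_overlapping
from .wavelets import WaveletKind, center_frequency, cwt_single_scale, dominant_frequency, scale_from_frequency

#: Orientation check: a correctly mounted AP axis yields negative
#: skewness of the detrended integrated signal; above this value the
#: axis is considered inverted and is flipped (with a warning).
_FLIP_SKEW_THRESHOLD = 0.1

#: Minimum separation between same-type candidates, as a fraction of the
#: dominant period (physiological refractory interval).
_MIN_SEPARATION_PERIODS = 0.25

#: Step-stage polarity per wavelet in home-like mode (chosen so the
#: retained extremum falls closest to the heel-strike instant).
_HOMELIKE_POLARITY = {WaveletKind.GAUS2: "max", WaveletKind.DB2: "min"}

#: The retained extremum leads the heel strike by about this fraction of
#: a step period (wavelet-dependent); context boundaries are shifted
#: earlier by the same amount so boundary steps keep their true context.
_HOMELIKE_LEAD_PERIODS = {WaveletKind.GAUS2: 0.21, WaveletKind.DB2: 0.11}
#: Extra grace (step periods) widening the turning window at its start /
#: narrowing shift at its end; boundary steps are ambiguous even for
#: human raters and the turn profile tails are below any rate floor.
_TURN_GRACE_START_PERIODS = 0.12
_TURN_GRACE_END_PERIODS = 0.05


class Polarity(str, enum.Enum):
    MIN = "MIN"
    MAX = "MAX"


@dataclass(frozen=True)
class CandidatePeak:
    """A candidate extremum of a differentiated signal."""

    index: int
    time: float
    magnitude: float
    polarity: Polarity


def find_candidate_peaks(coef: Series1D, polarity: Polarity, t0: float = 0.0) -> list[CandidatePeak]:
    """All local extrema of the requested polarity, as candidates.

    The magnitude is the signed height of the extremum in the oriented
    signal (negative-going minima of a MIN search have positive
    magnitude), mirroring how a mean-of-all-peaks threshold behaves.
    """
    y = -coef.values if polarity == Polarity.MIN else coef.values
    idx, _ = scipy.signal.find_peaks(y)
    return [
        CandidatePeak(int(i), t0 + i / coef.fs, float(y[i]), polarity) for i in idx
    ]


def threshold_peaks(cands: list[CandidatePeak], fraction: float) -> list[CandidatePeak]:
    """Retain candidates with magnitude > ``fraction`` x mean magnitude."""
    if not 0 < fraction < 1:
        raise ParameterError("fraction must be in (0, 1)")
    if not cands:
        return []
    cut = fraction * float(np.mean([c.magnitude for c in cands]))
    return [c for c in cands if c.magnitude > cut]


def threshold_cut(cands: list[CandidatePeak], fraction: float) -> float | None:
    """The absolute magnitude cut the 40% rule implies for ``cands``."""
    if not cands:
        return None
    return fraction * float(np.mean([c.magnitude for c in cands]))


def enforce_min_separation(cands: list[CandidatePeak], min_sep_s: float) -> list[CandidatePeak]:
    """Drop the weaker of any two candidates closer than ``min_sep_s``."""
    kept: list[CandidatePeak] = []
    for c in sorted(cands, key=lambda c: c.time):
        if kept and c.time - kept[-1].time < min_sep_s:
            if c.magnitude > kept[-1].magnitude:
                kept[-1] = c
        else:
            kept.append(c)
    return kept


def _alternate(hs: list[CandidatePeak], to: list[CandidatePeak]) -> list[tuple[float, EventType]]:
    """Enforce HS/TO alternation.

    HS events anchor the sequence; within each interval bounded by
    consecutive HS (and the open intervals before the first and after
    the last) only the strongest TO candidate survives, so exactly one
    TO separates neighbouring heel strikes.
    """
    hs = sorted(hs, key=lambda c: c.time)
    to = sorted(to, key=lambda c: c.time)
    if not hs:
        return [(c.time, EventType.TO) for c in to]
    hs_times = [c.time for c in hs]
    best: dict[int, CandidatePeak] = {}
    for c in to:
        slot = int(np.searchsorted(hs_times, c.time, side="right"))
        if slot not in best or c.magnitude > best[slot].magnitude:
            best[slot] = c
    events = [(c.time, EventType.HS) for c in hs]
    events += [(c.time, EventType.TO) for c in best.values()]
    return sorted(events)


def _preprocess_ap(ap: Series1D, params: PipelineParams) -> tuple[Series1D, Series1D, bool]:
    """detrend -> low-pass -> orientation check -> integrate."""
    x = lowpass(linear_detrend(ap), params.lowpass_cutoff_hz, params.filter_order)
    v = integrate_cumulative(x)
    flipped = False
    # orientation feature: skewness of the integrated signal with its
    # sub-gait drift removed (the raw integral random-walks on long
    # home-like sessions and would swamp the gait shape)
    drift = lowpass(v, min(0.3, 0.9 * params.dominant_freq_band_hz[0])).values
    sk = float(scipy.stats.skew(v.values - drift))
    if sk > _FLIP_SKEW_THRESHOLD:
        flipped = True
        warnings.warn(
            f"AP axis orientation looks inverted (integrated skewness {sk:.2f}); flipping",
            stacklevel=3,
        )
        x = Series1D(-x.values, x.fs)
        v = integrate_cumulative(x)
    return x, v, flipped


def _stage(series: Series1D, kind: WaveletKind, Fa: float, polarity: Polarity,
           params: PipelineParams, t0: float) -> tuple[list[CandidatePeak], list[CandidatePeak], Series1D, float]:
    """One CWT differentiation stage: returns (kept, rejected, coef, scale)."""
    a = scale_from_frequency(center_frequency(kind), Fa, 1.0 / series.fs)
    coef = cwt_single_scale(series, kind, a)
    cands = find_candidate_peaks(coef, polarity, t0)
    kept = threshold_peaks(cands, params.peak_threshold_fraction)
    rejected = [c for c in cands if c not in kept]
    kept = enforce_min_separation(kept, _MIN_SEPARATION_PERIODS / Fa)
    return kept, rejected, coef, a


def detect_hs_to(ap: Series1D, params: PipelineParams | None = None,
                 t0: float = 0.0) -> GaitEventList:
    """Detect alternating HS and TO events in a raw AP acceleration series.

    Returns an empty event list (with ``meta['warning']`` set) when the
    signal has no dominant frequency in the step band — e.g. when the
    wearer is not walking.
    """
    params = params or PipelineParams()
    if ap.n / ap.fs < 10.0:
        raise ParameterError("detect_hs_to needs at least 10 s of signal")
    x, v, flipped = _preprocess_ap(ap, params)
    try:
        Fa = dominant_frequency(x, params.dominant_freq_band_hz)
    except NoDominantFrequencyError as exc:
        warnings.warn(f"no steps detected: {exc}", stacklevel=2)
        return GaitEventList([], meta={"warning": str(exc), "flipped": flipped})

    hs_kept, hs_rej, d1, a1 = _stage(v, WaveletKind.GAUS1, Fa, Polarity.MIN, params, t0)
    to_kept, to_rej, d2, a2 = _stage(d1, WaveletKind.GAUS2, Fa, Polarity.MAX, params, t0)

    events = [GaitEvent(t, k) for t, k in _alternate(hs_kept, to_kept)]
    meta = {
        "dominant_frequency_hz": Fa,
        "scales": {"gaus1": a1, "gaus2": a2},
        "wavelets": ["gaus1", "gaus2"],
        "flipped": flipped,
        "rejected_times": {
            "HS": [c.time for c in hs_rej],
            "TO": [c.time for c in to_rej],
        },
    }
    return GaitEventList(events, meta=meta)


def detect_hs_to_recording(rec: InertialRecording,
                           params: PipelineParams | None = None) -> GaitEventList:
    """Run :func:`detect_hs_to` over each contiguous recording segment."""
    params = params or PipelineParams()
    events: list[GaitEvent] = []
    meta: dict = {"segments": []}
    for lo, hi in rec.segments:
        seg = Series1D(rec.ap[lo:hi], rec.fs)
        if seg.n / rec.fs < 10.0:
            continue
        res = detect_hs_to(seg, params, t0=rec.t0 + lo / rec.fs)
        events.extend(res.events)
        meta["segments"].append(res.meta)
    return GaitEventList(events, meta=meta)


def _context_segments(n: int, fs: float, t0: float,
                      windows: list[tuple[float, float]]) -> list[tuple[int, int, EventContext]]:
    """Split [0, n) into alternating non-turning / turning index ranges."""
    bounds: list[tuple[int, int, EventContext]] = []
    pos = 0
    for w0, w1 in windows:
        s = int(round((w0 - t0) * fs))
        e = int(round((w1 - t0) * fs))
        s, e = max(s, 0), min(e, n)
        if s > pos:
            bounds.append((pos, s, EventContext.NON_TURNING))
        if e > s:
            bounds.append((max(s, pos), e, EventContext.TURNING))
        pos = max(pos, e)
    if pos < n:
        bounds.append((pos, n, EventContext.NON_TURNING))
    return bounds


def _group_dominant_frequency(x: Series1D, segs: list[tuple[int, int, EventContext]],
                              context: EventContext, params: PipelineParams) -> float | None:
    """Dominant frequency over the concatenated samples of one context."""
    parts = [x.values[lo:hi] for lo, hi, ctx in segs if ctx == context]
    if not parts:
        return None
    cat = np.concatenate(parts)
    lo_hz = params.dominant_freq_band_hz[0]
    if len(cat) / x.fs < 4.0 / lo_hz:
        return None
    try:
        return dominant_frequency(Series1D(cat, x.fs), params.dominant_freq_band_hz)
    except NoDominantFrequencyError:
        return None


def detect_steps_homelike(rec: InertialRecording, turns: list[TurnInterval],
                          params: PipelineParams | None = None) -> GaitEventList:
    """Detect step (HS) events with context-adapted wavelets.

    The AP acceleration is split at the supplied turn boundaries; steps
    are detected with a gaus2 wavelet inside turning periods and a db2
    wavelet outside, each context keeping its own dominant frequency,
    scale and 40% threshold.  Segments shorter than three gait cycles
    borrow the threshold cut of the nearest long segment of the same
    context.  Only STEP events are emitted, labeled TURNING/NON_TURNING.
    """
    params = params or PipelineParams()
    turns = check_non_overlapping(list(turns))
    end_t = rec.t0 + rec.duration
    for t in turns:
        if t.start < rec.t0 - 1e-9 or t.end > end_t + 1e-9:
            raise ParameterError(f"turn [{t.start}, {t.end}] outside recording span")

    ap = Series1D(rec.ap, rec.fs)
    x, v, flipped = _preprocess_ap(ap, params)
    raw_windows = [(t.start, t.end) for t in turns]
    segs0 = _context_segments(rec.n, rec.fs, rec.t0, raw_windows)

    fa_by_ctx: dict[EventContext, float | None] = {}
    for ctx in (EventContext.TURNING, EventContext.NON_TURNING):
        fa_by_ctx[ctx] = _group_dominant_frequency(x, segs0, ctx, params)
    # fall back to the other context's estimate, then to the whole record
    if fa_by_ctx[EventContext.TURNING] is None:
        fa_by_ctx[EventContext.TURNING] = fa_by_ctx[EventContext.NON_TURNING]
    if fa_by_ctx[EventContext.NON_TURNING] is None:
        fa_by_ctx[EventContext.NON_TURNING] = fa_by_ctx[EventContext.TURNING]
    if all(v is None for v in fa_by_ctx.values()):
        try:
            fa = dominant_frequency(x, params.dominant_freq_band_hz)
        except NoDominantFrequencyError as exc:
            warnings.warn(f"no steps detected: {exc}", stacklevel=2)
            return GaitEventList([], meta={"warning": str(exc), "flipped": flipped})
        fa_by_ctx = {EventContext.TURNING: fa, EventContext.NON_TURNING: fa}

    # Each wavelet's retained extremum leads the heel strike by a known
    # fraction of a step period, so the context windows used to slice
    # that wavelet's candidates are shifted earlier accordingly; the
    # turning window gets a little extra grace at its start.
    fa_t = fa_by_ctx[EventContext.TURNING]
    fa_n = fa_by_ctx[EventContext.NON_TURNING]
    lead_g2 = _HOMELIKE_LEAD_PERIODS[WaveletKind.GAUS2] / fa_t
    start_shift = lead_g2 + _TURN_GRACE_START_PERIODS / fa_t
    end_shift = lead_g2 - _TURN_GRACE_END_PERIODS / fa_t
    lead_db2 = _HOMELIKE_LEAD_PERIODS[WaveletKind.DB2] / fa_n
    turn_windows = [(t.start - start_shift, max(t.end - end_shift, t.start - start_shift + 1e-6))
                    for t in turns]
    nonturn_windows = [(t.start - lead_db2, max(t.end - lead_db2, t.start - lead_db2 + 1e-6))
                       for t in turns]
    segs = (
        [s for s in _context_segments(rec.n, rec.fs, rec.t0, turn_windows)
         if s[2] == EventContext.TURNING]
        + [s for s in _context_segments(rec.n, rec.fs, rec.t0, nonturn_windows)
           if s[2] == EventContext.NON_TURNING]
    )
    segs.sort()

    kind_by_ctx = {EventContext.TURNING: WaveletKind.GAUS2,
                   EventContext.NON_TURNING: WaveletKind.DB2}
    coef_by_ctx: dict[EventContext, Series1D] = {}
    scale_by_ctx: dict[EventContext, float] = {}
    for ctx, kind in kind_by_ctx.items():
        fa = fa_by_ctx[ctx]
        a = scale_from_frequency(center_frequency(kind), fa, 1.0 / rec.fs)
        coef_by_ctx[ctx] = cwt_single_scale(v, kind, a)
        scale_by_ctx[ctx] = a

    # first pass: candidates + own threshold cut for long-enough segments
    seg_cands: list[list[CandidatePeak]] = []
    seg_cuts: list[float | None] = []
    for lo, hi, ctx in segs:
        coef = coef_by_ctx[ctx]
        pol = Polarity.MIN if _HOMELIKE_POLARITY[kind_by_ctx[ctx]] == "min" else Polarity.MAX
        piece = Series1D(coef.values[lo:hi], rec.fs) if hi - lo >= 3 else None
        cands = (find_candidate_peaks(piece, pol, t0=rec.t0 + lo / rec.fs)
                 if piece is not None else [])
        seg_cands.append(cands)
        fa = fa_by_ctx[ctx]
        long_enough = (hi - lo) / rec.fs >= 3.0 / fa
        seg_cuts.append(threshold_cut(cands, params.peak_threshold_fraction)
                        if long_enough else None)

    # second pass: short segments borrow the nearest long cut, same context
    picked: list[tuple[float, EventContext, float]] = []
    rejected: list[float] = []
    for i, (lo, hi, ctx) in enumerate(segs):
        cands = seg_cands[i]
        if not cands:
            continue
        cut = seg_cuts[i]
        if cut is None:
            mid = (lo + hi) / 2.0
            best = None
            for j, (lo2, hi2, ctx2) in enumerate(segs):
                if seg_cuts[j] is None or ctx2 != ctx:
                    continue
                d = abs((lo2 + hi2) / 2.0 - mid)
                if best is None or d < best[0]:
                    best = (d, seg_cuts[j])
            if best is None:
                pooled = [c for j, (l2, h2, c2) in enumerate(segs) if c2 == ctx
                          for c in seg_cands[j]]
                cut = threshold_cut(pooled, params.peak_threshold_fraction)
            else:
                cut = best[1]
        if cut is None:
            continue
        kept = [c for c in cands if c.magnitude > cut]
        rejected.extend(c.time for c in cands if c.magnitude <= cut)
        kept = enforce_min_separation(kept, _MIN_SEPARATION_PERIODS / fa_by_ctx[ctx])
        picked.extend((c.time, ctx, c.magnitude) for c in kept)

    # the two context windows may overlap slightly; drop duplicates,
    # preferring the turning label (the turn detector is authoritative)
    dedup_sep = 0.3 / max(fa_t, fa_n)
    events: list[GaitEvent] = []
    for t, ctx, mag in sorted(picked):
        if events and t - events[-1].time < dedup_sep:
            prev = events[-1]
            if ctx == EventContext.TURNING and prev.context != EventContext.TURNING:
                events[-1] = GaitEvent(t, EventType.STEP, ctx)
            continue
        events.append(GaitEvent(t, EventType.STEP, ctx))

    meta = {
        "flipped": flipped,
        "wavelets": {"turning": "gaus2", "non_turning": "db2"},
        "dominant_frequency_hz": {
            "turning": fa_by_ctx[EventContext.TURNING],
            "non_turning": fa_by_ctx[EventContext.NON_TURNING],
        },
        "scales": {"turning": scale_by_ctx[EventContext.TURNING],
                   "non_turning": scale_by_ctx[EventContext.NON_TURNING]},
        "n_segments": len(segs),
        "rejected_times": {"STEP": rejected},
    }
    return GaitEventList(events, meta=meta)
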