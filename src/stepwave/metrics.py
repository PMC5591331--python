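"""Agreement statistics between detected and reference gait events.

Matching uses a globally optimal one-to-one assignment (minimum total
absolute time difference) with a hard tolerance cap, so results do not
depend on list order.  Percentages are kept at full precision; the
display rounding used for reporting first rounds to one decimal and
then to an integer (half away from zero), which is the convention the
reference tables follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .errors import ParameterError
from .io import EventType, GaitEventList

_BIG = 1e9


@dataclass
class MatchResult:
    """Outcome of one-to-one event matching within a tolerance."""

    pairs: list[tuple[float, float]]
    tp: int
    fp: int
    fn: int
    diffs: np.ndarray

    def __post_init__(self) -> None:
        self.diffs = np.asarray(self.diffs, dtype=float)


@dataclass(frozen=True)
class ContingencyCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ParameterError("contingency counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ParameterError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class AgreementStats:
    """Percent-scale agreement metrics; NaN marks an undefined metric."""

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    kappa: float
    bland_mean: float | None = None
    bland_loa: tuple[float, float] | None = None

    def rounded(self) -> dict:
        keys = ("kappa", "accuracy", "sensitivity", "specificity", "npv", "ppv")
        return {k: round_display(getattr(self, k)) for k in keys}


def round_half_away(x: float) -> int:
    """Round half away from zero (3.5 -> 4, -3.5 -> -4)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def round_display(x: float) -> float | int:
    """Table display rounding: one decimal first, then integer."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    return round_half_away(round_half_away(x * 10.0) / 10.0)


def _as_times(events, expect_type: EventType | None = None) -> np.ndarray:
    if isinstance(events, GaitEventList):
        types = {e.type for e in events}
        if len(types) > 1:
            raise ParameterError(
                f"event list mixes types {sorted(t.value for t in types)}; match one type at a time"
            )
        if expect_type is not None and types and types != {expect_type}:
            raise ParameterError(
                f"event type mismatch: {types.pop().value} vs {expect_type.value}"
            )
        return events.times()
    return np.asarray(sorted(float(t) for t in events))


def match_events(detected, reference, tolerance: float = 0.3) -> MatchResult:
    """One-to-one matching of detected to reference event times.

    A detected event is a true positive when paired with a reference
    event less than ``tolerance`` seconds away; the pairing minimises
    the total absolute difference.  Unmatched detected events are false
    positives, unmatched reference events false negatives.
    """
    if tolerance < 0:
        raise ParameterError("tolerance must be non-negative")
    det = _as_times(detected)
    ref = _as_times(reference)
    if len(det) == 0 or len(ref) == 0:
        return MatchResult([], 0, len(det), len(ref), np.empty(0))
    cost = np.abs(det[:, None] - ref[None, :])
    cost = np.where(cost < tolerance, cost, _BIG)
    rows, cols = scipy.optimize.linear_sum_assignment(cost)
    pairs = [(float(det[i]), float(ref[j])) for i, j in zip(rows, cols)
             if cost[i, j] < _BIG]
    diffs = np.array([d - r for d, r in pairs])
    tp = len(pairs)
    return MatchResult(pairs, tp, len(det) - tp, len(ref) - tp, diffs)


def contingency_metrics(c: ContingencyCounts) -> AgreementStats:
    """Sensitivity/specificity/accuracy/PPV/NPV/kappa (percent scale).

    Metrics with a zero denominator come back as NaN rather than 0.
    Kappa is defined as 100 when observed agreement is perfect.
    """
    def ratio(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    n = c.total
    po = (c.tp + c.tn) / n
    pe = ((c.tp + c.fn) * (c.tp + c.fp) + (c.fp + c.tn) * (c.fn + c.tn)) / n ** 2
    if po >= 1.0:
        kappa = 100.0
    elif pe >= 1.0:
        kappa = float("nan")
    else:
        kappa = 100.0 * (po - pe) / (1.0 - pe)
    return AgreementStats(
        sensitivity=ratio(c.tp, c.tp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp),
        accuracy=ratio(c.tp + c.tn, n),
        ppv=ratio(c.tp, c.tp + c.fp),
        npv=ratio(c.tn, c.tn + c.fn),
        kappa=kappa,
    )


def lab_accuracy(n_detected: int, fp: int, fn: int) -> float:
    """Accuracy (%) for a design with no true negatives.

    ``tp = n_detected - fp``; accuracy = tp / (tp + fp + fn) * 100.
    """
    if fp > n_detected:
        raise ParameterError("false positives cannot exceed detections")
    if min(n_detected, fp, fn) < 0:
        raise ParameterError("counts must be non-negative")
    tp = n_detected - fp
    return 100.0 * tp / (tp + fp + fn)


def bland_altman(diffs) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement (mean ± 1.96 SD)."""
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) < 2:
        raise ParameterError("bland_altman needs at least 2 differences")
    m = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return m, m - 1.96 * sd, m + 1.96 * sd


def icc_two_raters(ratings_a, ratings_b) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure."""
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("ratings must be equal-length 1-D sequences")
    n = len(a)
    if n < 3:
        raise ParameterError("need at least 3 rated items")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ssb = k * float(np.sum((subj_means - grand) ** 2))
    ssc = n * float(np.sum((rater_means - grand) ** 2))
    sst = float(np.sum((data - grand) ** 2))
    sse = sst - ssb - ssc
    msr = ssb / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return float("nan")
    return (msr - mse) / denom


def contingency_from_detection(detected_times, rejected_times, truth_times,
                               tolerance: float = 0.3) -> ContingencyCounts:
    """Build a 2x2 table from a detection run against ground truth.

    TP/FP/FN come from one-to-one matching of retained detections; TN
    counts sub-threshold candidate extrema that do not correspond to a
    true step within the tolerance.
    """
    m = match_events(detected_times, truth_times, tolerance)
    rej = np.asarray(sorted(rejected_times), dtype=float)
    truth = np.asarray(sorted(truth_times), dtype=float)
    tn = 0
    for t in rej:
        if len(truth) == 0 or np.min(np.abs(truth - t)) >= tolerance:
            tn += 1
    return ContingencyCounts(tp=m.tp, fp=m.fp, fn=m.fn, tn=tn)
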