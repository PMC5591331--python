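import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stepwave as sw
from stepwave.errors import ParameterError
from stepwave.metrics import (
    ContingencyCounts,
    bland_altman,
    contingency_from_detection,
    contingency_metrics,
    icc_two_raters,
    lab_accuracy,
    match_events,
    round_display,
    round_half_away,
)


class TestMatchEvents:
    def test_rule_application(self):
        m = match_events([1.1, 2.5], [1.0, 2.0], 0.3)
        assert (m.tp, m.fp, m.fn) == (1, 1, 1)
        np.testing.assert_allclose(m.diffs, [0.1])

    def test_identical_lists(self):
        m = match_events([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.3)
        assert (m.tp, m.fp, m.fn) == (3, 0, 0)
        np.testing.assert_array_equal(m.diffs, 0.0)

    def test_closer_candidate_wins(self):
        m = match_events([0.95, 1.05], [1.0], 0.3)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert abs(m.diffs[0]) == pytest.approx(0.05)

    def test_empty_lists(self):
        m = match_events([], [1.0], 0.3)
        assert (m.tp, m.fp, m.fn) == (0, 0, 1)
        m = match_events([1.0], [], 0.3)
        assert (m.tp, m.fp, m.fn) == (0, 1, 0)

    def test_negative_tolerance(self):
        with pytest.raises(ParameterError):
            match_events([1.0], [1.0], -0.1)

    def test_strictly_below_tolerance(self):
        m = match_events([1.3], [1.0], 0.3)
        assert m.tp == 0  # "< 0.3 s", not <=

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 30), max_size=8, unique=True),
           st.lists(st.floats(0, 30), max_size=8, unique=True))
    def test_symmetry_swapping_lists(self, a, b):
        m1 = match_events(a, b, 0.3)
        m2 = match_events(b, a, 0.3)
        assert m1.tp == m2.tp and m1.fp == m2.fn and m1.fn == m2.fp

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(0, 12), min_size=1, max_size=6, unique=True),
           st.lists(st.floats(0, 12), min_size=1, max_size=6, unique=True))
    def test_exhaustive_assignment_oracle(self, det, ref):
        tol = 0.3
        m = match_events(det, ref, tol)
        # oracle: enumerate all injective assignments, maximise matches
        # then minimise total |diff|
        det_s, ref_s = sorted(det), sorted(ref)
        best = (0, 0.0)
        k = min(len(det_s), len(ref_s))
        for r in range(k, -1, -1):
            found = None
            for d_idx in itertools.combinations(range(len(det_s)), r):
                for r_perm in itertools.permutations(range(len(ref_s)), r):
                    diffs = [abs(det_s[i] - ref_s[j]) for i, j in zip(d_idx, r_perm)]
                    if all(d < tol for d in diffs):
                        tot = sum(diffs)
                        if found is None or tot < found:
                            found = tot
            if found is not None:
                best = (r, found)
                break
        assert m.tp == best[0]
        if m.tp:
            assert np.sum(np.abs(m.diffs)) == pytest.approx(best[1], abs=1e-9)


class TestContingencyMetrics:
    def test_pd_turning_row(self):
        stats = contingency_metrics(ContingencyCounts(tp=3257, fp=227, fn=361, tn=1083))
        assert stats.rounded() == {
            "kappa": 70, "accuracy": 88, "sensitivity": 90,
            "specificity": 83, "npv": 75, "ppv": 94,
        }
        # full-precision spot checks against hand arithmetic
        assert stats.sensitivity == pytest.approx(100 * 3257 / 3618)
        assert stats.specificity == pytest.approx(100 * 1083 / 1310)

    def test_perfect_agreement(self):
        stats = contingency_metrics(ContingencyCounts(tp=50, fp=0, fn=0, tn=50))
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv", "kappa"):
            assert getattr(stats, name) == pytest.approx(100.0)

    def test_chance_agreement_kappa_zero(self):
        stats = contingency_metrics(ContingencyCounts(tp=25, fp=25, fn=25, tn=25))
        assert stats.kappa == pytest.approx(0.0, abs=1e-12)

    def test_zero_denominator_is_nan_not_zero(self):
        stats = contingency_metrics(ContingencyCounts(tp=10, fp=0, fn=0, tn=0))
        assert np.isnan(stats.specificity)
        assert np.isnan(stats.npv)
        assert stats.kappa == 100.0  # po == 1

    def test_empty_table_rejected(self):
        with pytest.raises(ParameterError):
            ContingencyCounts(0, 0, 0, 0)

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_kappa_never_exceeds_accuracy(self, counts):
        tp, fp, fn, tn = counts
        if tp + fp + fn + tn == 0:
            counts = (1, 1, 1, 1)
            tp, fp, fn, tn = counts
        stats = contingency_metrics(ContingencyCounts(tp, fp, fn, tn))
        if not np.isnan(stats.kappa):
            assert stats.kappa <= stats.accuracy + 1e-9


class TestLabAccuracy:
    def test_hs_totals(self):
        acc = lab_accuracy(2729, 9, 10)
        assert acc == pytest.approx(100 * 2720 / 2739)
        assert round_display(acc) == 99

    def test_to_totals(self):
        acc = lab_accuracy(2732, 5, 12)
        assert acc == pytest.approx(100 * 2727 / 2744)
        assert round_display(acc) == 99

    def test_no_errors_is_100(self):
        assert lab_accuracy(100, 0, 0) == 100.0

    def test_fp_exceeding_detections_rejected(self):
        with pytest.raises(ParameterError):
            lab_accuracy(5, 6, 0)


class TestBlandAltman:
    def test_all_zero(self):
        assert bland_altman([0.0, 0.0, 0.0]) == (0.0, 0.0, 0.0)

    def test_two_symmetric_diffs(self):
        mean, lo, hi = bland_altman([0.1, -0.1])
        assert mean == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * np.std([0.1, -0.1], ddof=1), abs=1e-12)
        assert hi == pytest.approx(0.277, abs=1e-3)

    def test_monte_carlo_matches_closed_form(self):
        rng = np.random.default_rng(11)
        diffs = rng.normal(0.0, 0.05, 10_000)
        _, _, hi = bland_altman(diffs)
        assert 0.095 <= hi <= 0.101  # 1.96 * sigma = 0.098

    def test_too_few(self):
        with pytest.raises(ParameterError):
            bland_altman([0.1])


class TestICC:
    def test_identical_raters(self):
        a = [3.0, 5.0, 9.0, 2.0, 7.0]
        assert icc_two_raters(a, a) == pytest.approx(1.0)

    def test_constant_offset_matches_anova_oracle(self):
        a = np.array([10.0, 14.0, 18.0, 22.0, 30.0, 8.0])
        b = a + 4.0
        icc = icc_two_raters(a, b)
        oracle = _icc21_oracle(a, b)
        assert icc == pytest.approx(oracle, abs=1e-12)
        assert icc < 1.0  # bias term must reduce absolute agreement

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(2)
        a = rng.normal(10, 3, 30)
        b = a + rng.normal(0.5, 1.0, 30)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(30), 2),
            "raters": np.tile(["A", "B"], 30),
            "ratings": np.column_stack([a, b]).ravel(),
        })
        res = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="ratings")
        expected = float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_two_raters(a, b) == pytest.approx(expected, abs=1e-9)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=1000), rng.normal(size=1000)
        assert abs(icc_two_raters(a, b)) < 0.1

    def test_zero_variance_undefined(self):
        assert np.isnan(icc_two_raters([1.0] * 5, [1.0] * 5))


def _icc21_oracle(a, b):
    """ICC(2,1) with mean squares taken from a statsmodels ANOVA table."""
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    n = len(a)
    df = pd.DataFrame({
        "rating": np.concatenate([a, b]),
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat([0, 1], n),
    })
    aov = sm.stats.anova_lm(ols("rating ~ C(target) + C(rater)", df).fit())
    msr = aov.loc["C(target)", "mean_sq"]
    msc = aov.loc["C(rater)", "mean_sq"]
    mse = aov.loc["Residual", "mean_sq"]
    k = 2
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (93.484, 93), (93.5, 94), (-3.5, -4), (68.495, 68), (0.4, 0),
    ])
    def test_half_away(self, x, expected):
        assert round_half_away(x) == expected

    @pytest.mark.parametrize("x,expected", [
        (93.44, 93), (93.484, 94), (68.495, 69), (72.627, 73), (90.022, 90),
    ])
    def test_display_double_rounding(self, x, expected):
        assert round_display(x) == expected


class TestContingencyFromDetection:
    def test_tn_counts_rejected_nonsteps(self):
        truth = [1.0, 2.0, 3.0]
        detected = [1.05, 2.0]
        rejected = [1.1, 5.0, 6.0]  # 1.1 is near a true step: not a TN
        c = contingency_from_detection(detected, rejected, truth, 0.3)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 0, 1, 2)
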