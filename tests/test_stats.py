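import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from poised.stats import (CtMeasurement, ap_categorize, benjamini_hochberg,
                          comparative_ct, t_test_unpaired, wilcoxon_rank_sum)


def ct(target, ref, sample="s", group="test"):
    return CtMeasurement(sample, target, ref, group)


class TestComparativeCt:
    def test_self_calibration_is_one(self):
        m = ct(24.0, 18.0)
        assert comparative_ct(m, m) == 1.0

    @pytest.mark.parametrize("ddct,expected", [(1.0, 0.5), (-2.0, 4.0), (0.0, 1.0)])
    def test_closed_form(self, ddct, expected):
        test = ct(20.0 + ddct, 15.0)
        cal = ct(20.0, 15.0, group="calibrator")
        assert comparative_ct(test, cal) == pytest.approx(expected)

    def test_reference_shift_cancels(self):
        # shifting both target and reference Ct equally leaves expression unchanged
        a = comparative_ct(ct(22.0, 16.0), ct(20.0, 15.0))
        b = comparative_ct(ct(25.0, 19.0), ct(20.0, 15.0))
        assert a == pytest.approx(b)

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError):
            ct(0.0, 15.0)


class TestTTest:
    def test_identical_samples(self):
        t, p = t_test_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_clear_separation(self):
        _, p = t_test_unpaired([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert p < 0.01

    def test_pooled_formula_oracle(self):
        a = np.array([1.2, 2.4, 3.1, 4.9])
        b = np.array([2.2, 3.3, 4.1])
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2)
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        t, _ = t_test_unpaired(a, b)
        assert t == pytest.approx(t_hand, abs=1e-10)

    def test_swap_symmetry(self):
        a, b = [1.0, 3.0, 2.0], [4.0, 6.0, 5.0]
        t1, p1 = t_test_unpaired(a, b)
        t2, p2 = t_test_unpaired(b, a)
        assert t1 == -t2 and p1 == p2

    def test_degenerate_zero_variance(self):
        assert t_test_unpaired([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
        t, p = t_test_unpaired([3.0, 3.0], [2.0, 2.0])
        assert math.isinf(t) and p == 0.0

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            t_test_unpaired([1.0], [1.0, 2.0])

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(1.0, 2.0, size=6)
        t, p = t_test_unpaired(a, b, equal_var=False)
        ts, ps_ = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(float(ts)) and p == pytest.approx(float(ps_))


def rank_sum_enumeration(a, b):
    """Full enumeration oracle over all rank assignments (two-sided)."""
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    n, n_a = len(combined), len(a)
    w_obs = ranks[:n_a].sum()
    mu = ranks.sum() * n_a / n
    hits = total = 0
    for combo in itertools.combinations(range(n), n_a):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_extreme_small_case(self):
        # a={1,2}, b={3,4}: 2 of C(4,2)=6 assignments are as extreme -> 1/3
        _, p = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1.0 / 3.0)

    def test_identical_multisets_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 2.0], [1.0, 2.0, 2.0])
        assert p == 1.0

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.integers(0, 10, rng.integers(2, 6)).astype(float)
            b = rng.integers(0, 10, rng.integers(2, 6)).astype(float)
            _, p = wilcoxon_rank_sum(a, b)
            assert p == pytest.approx(rank_sum_enumeration(a, b))

    def test_u_statistic_matches_scipy(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=20), rng.normal(0.5, 1.0, size=25)
        u, p = wilcoxon_rank_sum(a, b)
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(float(res.statistic))
        assert p == pytest.approx(float(res.pvalue), rel=1e-6)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=15), rng.normal(size=18)
        _, p1 = wilcoxon_rank_sum(a, b)
        _, p2 = wilcoxon_rank_sum(b, a)
        assert p1 == pytest.approx(p2)

    def test_clear_shift_significant(self):
        a = np.arange(30, dtype=float)
        b = a + 50
        _, p = wilcoxon_rank_sum(a, b)
        assert p < 1e-6

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.02])[0] == pytest.approx(0.02)

    def test_step_up_arithmetic(self):
        # p(i) * n / i then cumulative min from the largest rank
        got = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        got = benjamini_hochberg(p)
        order = np.argsort(p)
        n = len(p)
        adj = p[order] * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        want = np.empty(n)
        want[order] = np.minimum(adj, 1.0)
        assert np.allclose(got, want)

    def test_never_decreases_and_preserves_order(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=30)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all()
        # order of significance preserved: q is non-decreasing along sorted p
        assert (np.diff(q[np.argsort(p)]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestApCategorize:
    def test_interpolated_cutoffs_and_assignment(self):
        control = list(range(1, 101))  # 1..100
        per_colony, fractions = ap_categorize(control, {"control": control,
                                                        "s": [95.0, 5.0, 20.0]})
        q10, q40 = fractions.attrs["cutoffs"]
        assert q10 == pytest.approx(10.9)
        assert q40 == pytest.approx(40.6)
        s = per_colony[per_colony["sample"] == "s"]
        assert list(s["category"]) == ["high", "low", "intermediate"]

    def test_control_fractions_are_60_30_10(self):
        control = list(range(1, 101))
        _, fractions = ap_categorize(control, {"control": control})
        row = fractions.loc["control"]
        assert row["low"] == pytest.approx(0.10)
        assert row["intermediate"] == pytest.approx(0.30)
        assert row["high"] == pytest.approx(0.60)

    def test_degenerate_equal_control(self):
        # all control intensities equal: boundary ties go to "low"
        _, fractions = ap_categorize([5.0] * 10, {"s": [5.0]})
        assert fractions.loc["s", "low"] == 1.0

    def test_large_sample_fractions_converge(self):
        rng = np.random.default_rng(6)
        control = rng.lognormal(0, 0.5, 5000)
        _, fractions = ap_categorize(control, {"control": control})
        row = fractions.loc["control"]
        assert abs(row["low"] - 0.10) < 0.02
        assert abs(row["intermediate"] - 0.30) < 0.02
        assert abs(row["high"] - 0.60) < 0.02

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            ap_categorize([], {"s": [1.0]})
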