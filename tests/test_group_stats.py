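"""Nonparametric group tests against brute-force enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from envdecode.group_stats import (SubjectRecord, band_cross_correlation,
                                   by_adjust, kruskal_variance,
                                   order_effect_sign_test, paired_wilcoxon,
                                   ratio_test, robust_regress)


def signed_rank_oracle(diffs):
    """Exhaustive signed-rank null: every sign pattern, average ranks."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    w_all = [np.sum(np.array(signs) * ranks)
             for signs in itertools.product([0, 1], repeat=n)]
    w_all = np.asarray(w_all, dtype=float)
    p_le = np.mean(w_all <= w_obs + 1e-12)
    p_ge = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


def by_oracle(p):
    """Direct-definition BY adjustment: min over j >= rank of p_(j)*m*c/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    c = sum(1.0 / k for k in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [p[order[j]] * m * c / (j + 1) for j in range(pos, m)]
        out[idx] = min(candidates)
    return out


class TestPairedWilcoxon:
    def test_identical_samples_give_p_one(self):
        a = np.arange(8.0)
        rep = paired_wilcoxon(a, a)
        assert rep.raw_p == 1.0

    def test_uniform_shift_n16_matches_exact_all_positive_tail(self):
        a = np.arange(16.0)
        rep = paired_wilcoxon(a + 1, a)
        assert rep.raw_p == pytest.approx(2 / 2 ** 16, rel=1e-12)

    def test_reversed_sequence_matches_enumeration_oracle(self):
        a = np.arange(1.0, 7.0)
        b = a[::-1]
        rep = paired_wilcoxon(a, b)
        assert rep.raw_p == pytest.approx(signed_rank_oracle(a - b), rel=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_small_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        a = rng.normal(0, 1, n).round(2)  # rounding induces rank ties
        b = rng.normal(0.3, 1, n).round(2)
        rep = paired_wilcoxon(a, b)
        assert rep.raw_p == pytest.approx(signed_rank_oracle(a - b), rel=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1, 2], [2, 3])


class TestRatioTest:
    def test_equal_conditions_give_p_one(self):
        a = np.linspace(0.1, 0.3, 8)
        assert ratio_test(a, a).raw_p == 1.0

    def test_doubled_values_reach_smallest_attainable_p(self):
        unaided = np.linspace(0.1, 0.3, 10)
        rep = ratio_test(2 * unaided, unaided)
        assert rep.raw_p == pytest.approx(2 / 2 ** 10, rel=1e-12)

    def test_zero_unaided_subjects_excluded_with_warning(self):
        aided = np.linspace(0.1, 0.3, 8)
        unaided = aided.copy()
        unaided[0] = 0.0
        with pytest.warns(RuntimeWarning):
            rep = ratio_test(aided, unaided)
        assert rep.n == 7

    def test_log_symmetric_null_rejects_at_alpha(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            ratios = np.exp(rng.normal(0, 0.4, 16))
            if paired_wilcoxon(ratios, np.ones(16)).raw_p < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert 0.02 < rate < 0.09  # ~alpha, binomial slack at 400 reps


class TestKruskalVariance:
    def test_identical_samples_give_h_zero(self):
        a = np.arange(10.0)
        rep = kruskal_variance(a, a.copy())
        assert rep.statistic == 0.0

    def test_pure_location_shift_not_flagged_as_dispersion(self):
        rng = np.random.default_rng(1)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            a = rng.normal(0, 1, 17)
            b = rng.normal(5, 1, 17)  # same spread, shifted location
            if kruskal_variance(a, b).raw_p < 0.05:
                hits += 1
        assert hits / n_rep < 0.1

    def test_tenfold_spread_detected(self):
        rng = np.random.default_rng(2)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            a = rng.normal(0, 1, 17)
            b = rng.normal(0, 10, 17)
            if kruskal_variance(a, b).raw_p < 0.05:
                hits += 1
        assert hits / n_rep > 0.9

    def test_raw_mode_responds_to_location(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 17)
        b = rng.normal(5, 1, 17)
        assert kruskal_variance(a, b, raw=True).raw_p < 0.01


class TestByAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(by_adjust([0.04]), [0.04])

    def test_hand_computed_three_value_family(self):
        adj = by_adjust([0.01, 0.02, 0.03])
        np.testing.assert_allclose(adj, [0.055, 0.055, 0.055], rtol=1e-12)

    def test_values_may_exceed_one_uncapped(self):
        adj = by_adjust([0.9, 0.95])
        assert np.all(adj > 1.0)

    def test_empty_input(self):
        assert by_adjust([]).size == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_direct_definition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, int(rng.integers(2, 9)))
        np.testing.assert_allclose(by_adjust(p), by_oracle(p), rtol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_monotone_and_dominates_raw(self, p_values):
        p = np.asarray(p_values)
        adj = by_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestRobustRegress:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 1, 20)
        fit = robust_regress(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-8)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)

    def test_single_gross_outlier_barely_moves_slope(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 1, 15)
        y = 1.5 * x + 0.2 + rng.normal(0, 0.02, 15)
        clean_slope = np.polyfit(x[:-1], y[:-1], 1)[0]
        y_out = y.copy()
        y_out[-1] += 50.0
        fit = robust_regress(x, y_out)
        assert fit.slope == pytest.approx(clean_slope, rel=0.05)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.normal(0, 1, 16)
            y = rng.normal(0, 1, 16)
            if robust_regress(x, y).p_value < 0.05:
                hits += 1
        rate = hits / n_rep
        assert rate < 0.12  # large-sample z test is mildly liberal at n=16

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            robust_regress(np.ones(10), np.arange(10.0))


class TestOrderEffectSignTest:
    def test_balanced_signs_give_p_one(self):
        first = np.concatenate([np.ones(8), -np.ones(8)])
        rep = order_effect_sign_test(first, np.zeros(16))
        assert rep.raw_p == 1.0

    def test_all_positive_16_matches_binomial_tail(self):
        rep = order_effect_sign_test(np.ones(16), np.zeros(16))
        assert rep.raw_p == pytest.approx(2 / 2 ** 16, rel=1e-12)

    def test_twelve_of_sixteen_positive(self):
        first = np.concatenate([np.ones(12), -np.ones(4)])
        rep = order_effect_sign_test(first, np.zeros(16))
        expected = 2 * sum(__import__("math").comb(16, k)
                           for k in range(12, 17)) / 2 ** 16
        assert rep.raw_p == pytest.approx(expected, rel=1e-12)

    def test_ties_dropped_and_all_ties_give_p_one(self):
        rep = order_effect_sign_test(np.ones(6), np.ones(6))
        assert rep.raw_p == 1.0 and rep.notes == "all ties"


def _records(rng, n=12, duplicate_wide_from_delta=False):
    rows = []
    for i in range(n):
        for cond in ("aided", "unaided"):
            delta = float(rng.uniform(0.05, 0.25))
            theta = float(rng.uniform(0.05, 0.25))
            wide = delta if duplicate_wide_from_delta else float(
                rng.uniform(0.05, 0.25))
            for band, r in (("delta", delta), ("theta", theta), ("wide", wide)):
                rows.append(SubjectRecord(f"S{i:02d}", band, cond, r))
    return rows


class TestBandCrossCorrelation:
    def test_duplicated_band_has_unit_correlation(self):
        rng = np.random.default_rng(6)
        table = band_cross_correlation(_records(rng, duplicate_wide_from_delta=True))
        dup = table[(table.x_band == "delta") & (table.y_band == "wide")]
        assert np.allclose(dup.pearson_r, 1.0)

    def test_nine_tests_form_one_adjustment_family(self):
        rng = np.random.default_rng(7)
        table = band_cross_correlation(_records(rng))
        assert len(table) == 9  # 3 pairs x (2 conditions + ratio)
        np.testing.assert_allclose(table.adjusted_p.to_numpy(),
                                   by_adjust(table.raw_p.to_numpy()))

    def test_independent_bands_rarely_significant_after_adjustment(self):
        rng = np.random.default_rng(8)
        sig = 0
        n_rep = 60
        for _ in range(n_rep):
            table = band_cross_correlation(_records(rng))
            sig += int((table.adjusted_p < 0.05).any())
        assert sig / n_rep <= 0.1

    def test_incomplete_subject_dropped_with_warning(self):
        rng = np.random.default_rng(9)
        records = _records(rng)[:-1]  # drop one band row of the last subject
        with pytest.warns(RuntimeWarning):
            table = band_cross_correlation(records)
        assert len(table) == 9


class TestSubjectRecordValidation:
    def test_rejects_out_of_range_proportion(self):
        with pytest.raises(ValueError):
            SubjectRecord("S01", "delta", "aided", 0.1, behavioral_bkb=1.4)

    def test_rejects_non_finite_mean_r(self):
        with pytest.raises(ValueError):
            SubjectRecord("S01", "delta", "aided", float("nan"))
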