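import itertools
import math
from math import comb

import numpy as np
import pytest
from scipy import stats

from meioco import count_stats as cs
from meioco import simulate
from meioco.count_stats import (
    ReconstructionError, fisher_exact_2x2, fold_change, focus_number_distribution,
    g_test, mann_whitney, rate_comparison, reconstruct_count, summarize_focus_counts,
)
from meioco.io_types import FocusTable

from conftest import make_rows


class TestSummaries:
    def test_constant_counts(self):
        s = summarize_focus_counts([18, 18, 18])
        assert (s.mean, s.sd, s.n) == (18.0, 0.0, 3)

    def test_closed_form_sd(self):
        s = summarize_focus_counts([1, 2, 3, 4])
        assert s.mean == 2.5
        assert s.sd == pytest.approx(1.2909944, abs=1e-6)

    def test_simulated_pachytene_counts_match_reported_mean(self, rng):
        model = simulate.count_model("RAD51/DMC1", "pachynema", "wild-type", n_cells=200)
        s = summarize_focus_counts(simulate.simulate_stage_counts(model, rng))
        assert s.mean == pytest.approx(18.2, abs=2 * 7.0 / np.sqrt(200))


class TestFoldChange:
    def test_reported_pachytene_fold(self):
        assert fold_change(131.0, 18.2).rounded == 7.2

    def test_reported_dmc1_fold_consistent_with_bound(self):
        fc = fold_change(147.8, 0.4)
        assert fc.rounded == 369.5
        assert fc.ratio > 300

    def test_identity(self):
        assert fold_change(5.5, 5.5).rounded == 1.0

    def test_reciprocal_product_is_one_before_rounding(self, rng):
        a, b = rng.uniform(1, 100, 2)
        assert fold_change(a, b).ratio * fold_change(b, a).ratio == pytest.approx(1.0)

    def test_rounding_conventions(self):
        assert fold_change(83.4, 10.0, "nearest-integer").rounded == 8
        assert fold_change(602, 10.0, "nearest-ten").rounded == 60.0
        with pytest.raises(ValueError):
            fold_change(1.0, 2.0, "bogus")

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration of the two-sided p."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)

    def pr(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = pr(a)
    return sum(pr(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if pr(x) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_identical_rows_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).pvalue == 1.0

    def test_diagonal_table_enumeration(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]).pvalue == pytest.approx(1 / 3)

    def test_zero_margin_degenerate(self):
        r = fisher_exact_2x2([[0, 0], [3, 4]])
        assert r.pvalue == 1.0 and r.extra["degenerate"]

    def test_matches_enumeration_oracle_small_tables(self):
        for a, b, c, d in itertools.product(range(6), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            p = fisher_exact_2x2([[a, b], [c, d]]).pvalue
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)

    def test_reported_achiasmate_comparison(self):
        # 3.0% of 1808 vs 1.1% of 1083 achiasmate pairs
        a = reconstruct_count(3.0, 1808)
        b = reconstruct_count(1.1, 1083)
        p = fisher_exact_2x2([[a, 1808 - a], [b, 1083 - b]]).pvalue
        assert round(p, 4) == 0.0008


class TestGTest:
    def test_observed_equals_expected(self):
        r = g_test([[10, 10], [10, 10]])
        assert (r.statistic, r.pvalue) == (0.0, 1.0)

    def test_direct_formula_example(self):
        r = g_test([[10, 20], [20, 10]])
        assert r.statistic == pytest.approx(6.80, abs=5e-3)
        assert r.df == 1

    def test_zero_margin_suggests_pooling(self):
        with pytest.raises(ValueError, match="pool"):
            g_test([[0, 0], [3, 4]])

    def test_additive_under_proportional_refinement(self):
        # splitting a column into proportional halves leaves G unchanged
        base = np.array([[30, 60], [50, 20]])
        refined = np.array([[30, 30, 30], [50, 10, 10]])
        assert g_test(refined).statistic == pytest.approx(g_test(base).statistic, abs=1e-10)

    def test_williams_correction_shrinks_g(self):
        plain = g_test([[16, 404], [3, 329]])
        corrected = g_test([[16, 404], [3, 329]], williams=True)
        assert corrected.statistic < plain.statistic


def mw_enumeration_oracle(x, y):
    """Literal split enumeration of the two-sided exact p."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_identical_samples_exact_p_one(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3]).pvalue == 1.0

    def test_fully_separated_small_samples(self):
        r = mann_whitney([1, 2, 3], [10, 11, 12])
        assert (r.statistic, r.pvalue) == (0.0, 0.1)
        assert r.extra["mode"] == "exact"

    def test_exact_matches_split_enumeration_with_ties(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(2, 7), rng.integers(2, 7)
            x = rng.integers(0, 5, n1).astype(float)
            y = rng.integers(0, 5, n2).astype(float)
            assert mann_whitney(x, y).pvalue == pytest.approx(
                mw_enumeration_oracle(x, y), abs=1e-9)

    def test_exact_and_asymptotic_agree_on_poisson_counts(self, rng):
        diffs = []
        for _ in range(10):
            x, y = rng.poisson(20, 15), rng.poisson(22, 15)
            pe = mann_whitney(x, y, method="exact").pvalue
            pa = mann_whitney(x, y, method="asymptotic").pvalue
            diffs.append(abs(pe - pa))
        assert max(diffs) < 0.02

    def test_large_samples_use_asymptotic(self, rng):
        r = mann_whitney(rng.normal(0, 1, 25), rng.normal(0, 1, 25))
        assert r.extra["mode"] == "asymptotic"


class TestFocusNumberDistribution:
    def test_two_bivalent_example(self):
        t = FocusTable.from_rows(make_rows([("c", 1, 10.0, [0.5]), ("c", 2, 9.0, None)]))
        fractions, N = focus_number_distribution(t)
        assert N == 2
        assert fractions[0] == fractions[1] == 0.5

    def test_obligate_perfect_detection_no_zero_class(self):
        import dataclasses
        params = dataclasses.replace(simulate.wild_type_params(seed=2, n_cells=10),
                                     detection_efficiency=1.0)
        fractions, N = focus_number_distribution(simulate.simulate_dataset(params))
        assert N == 190 and fractions[0] == 0.0

    def test_fractions_reproduce_integer_counts(self, wt_small):
        fractions, N = focus_number_distribution(wt_small)
        assert sum(fractions.values()) == pytest.approx(1.0)
        for frac in fractions.values():
            assert frac * N == pytest.approx(round(frac * N))


class TestRateComparison:
    def test_reported_xy_asynapsis_folds(self):
        # 6.5% (10/154) vs 0.9% (1/116): fold of the one-decimal rates
        r = rate_comparison(10, 154, 1, 116)
        assert (r.rate_a, r.rate_b, r.fold) == (6.5, 0.9, 7.2)
        r60 = rate_comparison(13, 24, 1, 116, rounding="nearest-integer")
        assert (r60.rate_a, r60.fold) == (54.2, 60)

    def test_equal_rates(self):
        r = rate_comparison(5, 50, 5, 50)
        assert r.fold == 1.0 and r.fisher.pvalue == 1.0

    def test_zero_denominator_rate_infinite_fold(self):
        r = rate_comparison(5, 50, 0, 80)
        assert math.isinf(r.fold)

    def test_validation(self):
        with pytest.raises(ValueError):
            rate_comparison(5, 4, 1, 10)


class TestReconstruction:
    @pytest.mark.parametrize("percent,n,count", [
        (32.5, 416, 135), (56.0, 416, 233), (30.7, 202, 62), (58.4, 202, 118),
        (3.0, 1808, 54), (1.1, 1083, 12), (6.5, 154, 10), (0.9, 116, 1),
        (3.8, 420, 16), (0.9, 332, 3), (19.5, 231, 45), (10.6, 273, 29),
    ])
    def test_reported_percentages_reconstruct(self, percent, n, count):
        assert reconstruct_count(percent, n) == count

    def test_failing_reconstruction_refused(self):
        with pytest.raises(ReconstructionError):
            reconstruct_count(10.0, 7)  # round(0.7)=1 -> 14.3%, not 10.0%


class TestTypeIErrorCalibration:
    def test_null_rejection_rates_near_alpha(self, rng):
        # simulated null: each test's empirical size at alpha=0.05
        n_rep = 10_000
        # G test on 2x2 tables from two binomials (n=100, p=0.3)
        a = rng.binomial(100, 0.3, n_rep)
        b = rng.binomial(100, 0.3, n_rep)
        rej = 0
        for ai, bi in zip(a, b):
            if min(ai + bi, 200 - ai - bi) == 0:
                continue
            if g_test([[ai, 100 - ai], [bi, 100 - bi]]).pvalue < 0.05:
                rej += 1
        assert rej / n_rep == pytest.approx(0.05, abs=0.02)

        # Mann-Whitney (asymptotic path) on normal samples
        x = rng.normal(0, 1, (n_rep, 30))
        y = rng.normal(0, 1, (n_rep, 30))
        rej = sum(mann_whitney(xi, yi).pvalue < 0.05 for xi, yi in zip(x, y))
        assert rej / n_rep == pytest.approx(0.05, abs=0.02)

    def test_fisher_null_size_not_anticonservative(self, rng):
        # exact test: size must stay at or below alpha (discreteness makes it
        # conservative), and within the calibration band below it
        n_rep = 10_000
        a = rng.binomial(100, 0.3, n_rep)
        b = rng.binomial(100, 0.3, n_rep)
        rej = sum(fisher_exact_2x2([[ai, 100 - ai], [bi, 100 - bi]]).pvalue < 0.05
                  for ai, bi in zip(a, b))
        assert 0.03 <= rej / n_rep <= 0.05
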