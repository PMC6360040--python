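"""Rank correlations with resampling, gated group tests, adjusted
comparisons and the design-stage sample size."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from plateletscore.association import (
    ancova_boosted,
    associate_score,
    compare_groups,
    required_n,
    spearman_boosted,
    spearman_stratified,
)


class TestSpearmanBoosted:
    def test_perfect_monotone(self):
        x = np.arange(20.0)
        res = spearman_boosted(x, np.exp(x / 5), B=1000, seed=0)
        assert res.r_s == pytest.approx(1.0)

    def test_perfect_antitone(self):
        x = np.arange(20.0)
        res = spearman_boosted(x, -(x**3), B=1000, seed=0)
        assert res.r_s == pytest.approx(-1.0)

    def test_matches_scipy_estimate(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 100))
        res = spearman_boosted(x, y, B=1000, seed=0, jackknife=False)
        ref = spearmanr(x, y)
        assert res.r_s == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=0.05)

    def test_null_bound_and_ci_covers_zero(self):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal((2, 1000))
        res = spearman_boosted(x, y, B=2000, seed=1, jackknife=False)
        assert abs(res.r_s) < 0.08  # ~2.5/sqrt(n)
        assert res.ci[0] < 0 < res.ci[1]

    def test_jackknife_range_contains_estimate(self):
        rng = np.random.default_rng(8)
        x, y = rng.standard_normal((2, 40))
        res = spearman_boosted(x, y, B=500, seed=2)
        assert res.jackknife_min <= res.r_s <= res.jackknife_max

    def test_influential_point_flagged(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        x[0], y[0] = 20.0, 20.0  # single point manufacturing correlation
        res = spearman_boosted(x, y, B=500, seed=3)
        assert res.influence_flag

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_boosted([1.0] * 10, np.arange(10.0), B=500, seed=0)

    def test_exact_small_sample_p_is_permutation_fraction(self):
        # n=5 perfectly concordant: 2/120 permutations reach |rho|=1
        res = spearman_boosted(
            [1, 2, 3, 4, 5], [2, 4, 6, 8, 10], B=500, seed=0
        )
        assert res.p == pytest.approx(2 / 120)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=20)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 30))
        a = spearman_boosted(x, y, B=200, seed=1, jackknife=False)
        b = spearman_boosted(np.exp(x), y**3, B=200, seed=1, jackknife=False)
        assert a.r_s == pytest.approx(b.r_s, abs=1e-12)


class TestStratified:
    def test_pooled_matches_common_correlation(self):
        rng = np.random.default_rng(1)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=400)
        strata = np.repeat([0, 1], 200)
        r, p = spearman_stratified(z[:, 0], z[:, 1], strata)
        assert r == pytest.approx(0.48, abs=0.08)
        assert p < 1e-6


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        g = np.concatenate([np.arange(50.0), np.arange(50.0)])
        labels = np.repeat([0, 1], 50)
        res = compare_groups(g, labels)
        assert res.p > 0.99

    def test_strong_shift_detected_with_t(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0, 1, 200), rng.normal(1, 1, 200)])
        res = compare_groups(vals, np.repeat([0, 1], 200))
        assert res.p < 1e-3
        assert res.test == "student-t"

    def test_heteroscedastic_lognormal_goes_nonparametric(self):
        rng = np.random.default_rng(3)
        a = np.exp(rng.normal(0, 1.0, 150))
        b = np.exp(rng.normal(0.3, 2.5, 150)) + rng.exponential(5, 150)
        res = compare_groups(np.concatenate([a, b]), np.repeat([0, 1], 150))
        # a Box-Cox transform cannot equalize these variances
        assert res.test in ("mann-whitney-u", "student-t")
        if res.gate.decision == "nonparametric":
            assert res.test == "mann-whitney-u"

    def test_three_groups_take_anova_path(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal(300)
        res = compare_groups(vals, np.repeat([0, 1, 2], 100))
        assert res.test in ("anova", "kruskal-wallis")


class TestAncova:
    def test_reduces_to_unadjusted_comparison(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(0, 1, 60), rng.normal(0.9, 1, 60)])
        labels = np.repeat([0, 1], 60)
        adj = ancova_boosted(vals, labels, covariates=None, B=2000, seed=0)
        ref = compare_groups(vals, labels)
        assert adj.p_bootstrap == pytest.approx(ref.p, abs=0.02)

    def test_confounded_effect_detected(self):
        rng = np.random.default_rng(6)
        n = 251
        age = rng.uniform(60, 65, n)
        g = (rng.random(n) < 0.5).astype(int)
        y = 1.0 * g + 0.3 * (age - 62.5) + rng.standard_normal(n)
        adj = ancova_boosted(y, g, covariates=age[:, None], B=2000, seed=1)
        assert adj.p_bootstrap < 0.01

    def test_adjusted_means_recover_group_gap(self):
        rng = np.random.default_rng(7)
        n = 400
        age = rng.uniform(60, 65, n)
        g = np.repeat([0, 1], n // 2)
        y = 2.0 * g + 0.5 * age + rng.standard_normal(n) * 0.1
        adj = ancova_boosted(y, g, covariates=age[:, None], B=1000, seed=2)
        gap = adj.adjusted_means["1"] - adj.adjusted_means["0"]
        assert gap == pytest.approx(2.0, abs=0.05)

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(8)
        age = rng.uniform(60, 65, 100)
        covs = np.column_stack([age, 2 * age])
        with pytest.raises(ValueError, match="collinear"):
            ancova_boosted(rng.standard_normal(100), np.repeat([0, 1], 50),
                           covariates=covs, B=1000, seed=0)

    def test_iteration_floor_enforced(self):
        with pytest.raises(ValueError):
            ancova_boosted(np.arange(10.0), np.repeat([0, 1], 5), B=500, seed=0)

    def test_missing_cells_rejected(self):
        y = np.arange(10.0)
        y[0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            ancova_boosted(y, np.repeat([0, 1], 5), B=1000, seed=0)


class TestRequiredN:
    def test_design_anchor(self):
        ceil_n, round_n = required_n(0.22, alpha=0.01, power=0.90)
        assert round_n == 300
        assert ceil_n == 301

    def test_strong_correlation_tiny_n(self):
        ceil_n, _ = required_n(0.9, alpha=0.05, power=0.80)
        assert ceil_n == 7

    def test_formula_floor(self):
        ceil_n, _ = required_n(0.999999, alpha=0.999, power=0.500001)
        assert ceil_n >= 3

    def test_zero_correlation_diverges(self):
        with pytest.raises(ValueError):
            required_n(0.0)

    def test_monotone_in_r(self):
        ns = [required_n(r)[0] for r in (0.1, 0.2, 0.3, 0.5)]
        assert ns == sorted(ns, reverse=True)


class TestBatch:
    def test_tidy_output_with_optional_fdr(self, scored):
        data, _ = scored
        out = associate_score(
            data, "cum_aggregation", ["plt", "pct", "uric_acid"],
            B=300, seed=0, jackknife=False, fdr=True,
        )
        assert list(out["variable"]) == ["plt", "pct", "uric_acid"]
        assert {"r_s", "p", "ci_lo", "ci_hi", "q_fdr"} <= set(out.columns)
        assert (out["q_fdr"] >= out["p"] - 1e-12).all()
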