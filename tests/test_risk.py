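"""Odds ratios, Mantel-Haenszel pooling, logistic fits and forest data."""

import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.contingency_tables import StratifiedTable

from plateletscore.risk import build_forest, fit_logistic, mh_pooled, or_2x2


def mh_brute_force(strata):
    """Direct arithmetic oracle for the MH point estimate."""
    num = den = 0.0
    for t in strata:
        (a, b), (c, d) = t
        n = a + b + c + d
        num += a * d / n
        den += b * c / n
    return num / den


class TestOr2x2:
    def test_symmetric_table_unity(self):
        assert or_2x2([[10, 10], [10, 10]]).odds_ratio == pytest.approx(1.0)

    def test_hand_value(self):
        assert or_2x2([[20, 10], [10, 20]]).odds_ratio == pytest.approx(4.0)

    def test_continuity_correction_hand_oracle(self):
        res = or_2x2([[5, 0], [5, 5]])
        assert res.corrected
        expected = (5.5 * 5.5) / (0.5 * 5.5)
        assert res.odds_ratio == pytest.approx(expected, abs=1e-12)

    def test_woolf_ci_hand_oracle(self):
        res = or_2x2([[20, 10], [10, 20]])
        se = math.sqrt(1 / 20 + 1 / 10 + 1 / 10 + 1 / 20)
        lo = math.exp(math.log(4) - 1.959963984540054 * se)
        assert res.ci[0] == pytest.approx(lo, rel=1e-9)

    def test_empty_margin_undefined(self):
        with pytest.raises(ValueError, match="margin"):
            or_2x2([[0, 0], [5, 5]])

    def test_non_integer_cells_rejected(self):
        with pytest.raises(ValueError):
            or_2x2([[1.5, 2], [3, 4]])


class TestMhPooled:
    def test_single_stratum_identity(self):
        t = [[20, 10], [10, 20]]
        assert mh_pooled([t]).odds_ratio == pytest.approx(
            or_2x2(t).odds_ratio, abs=1e-12
        )

    def test_homogeneous_copies(self):
        t = [[20, 10], [10, 20]]
        assert mh_pooled([t] * 5).odds_ratio == pytest.approx(4.0, abs=1e-12)

    @pytest.mark.parametrize(
        "strata",
        [
            [[[12, 7], [9, 14]], [[30, 20], [18, 35]]],
            [[[5, 9], [11, 4]], [[20, 16], [9, 22]], [[7, 7], [8, 6]]],
            [
                [[12, 7], [9, 14]], [[30, 20], [18, 35]], [[5, 9], [11, 4]],
                [[20, 16], [9, 22]], [[7, 7], [8, 6]],
            ],
        ],
    )
    def test_matches_brute_force_formula(self, strata):
        assert mh_pooled(strata).odds_ratio == pytest.approx(
            mh_brute_force(strata), abs=1e-12
        )

    def test_matches_statsmodels_estimate_and_ci(self):
        strata = [[[12, 7], [9, 14]], [[30, 20], [18, 35]]]
        ours = mh_pooled(strata)
        ref = StratifiedTable([np.array(t) for t in strata])
        assert ours.odds_ratio == pytest.approx(ref.oddsratio_pooled, rel=1e-10)
        lo, hi = ref.oddsratio_pooled_confint()
        assert ours.ci[0] == pytest.approx(lo, rel=1e-6)
        assert ours.ci[1] == pytest.approx(hi, rel=1e-6)

    def test_transposing_margins_inverts_or(self):
        strata = [[[12, 7], [9, 14]], [[30, 20], [18, 35]]]
        flipped = [[[t[0][1], t[0][0]], [t[1][1], t[1][0]]] for t in strata]
        a = mh_pooled(strata).odds_ratio
        b = mh_pooled(flipped).odds_ratio
        assert a == pytest.approx(1 / b, rel=1e-12)

    def test_all_zero_cross_products(self):
        # ad = bc = 0 in every stratum: nothing to estimate
        with pytest.raises(ValueError):
            mh_pooled([[[5, 0], [5, 0]], [[3, 0], [3, 0]]])

    def test_one_sided_zeros_continuity_corrected(self):
        res = mh_pooled([[[5, 0], [0, 5]], [[3, 0], [0, 3]]])
        assert res.corrected
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 1


class TestLogistic:
    def test_null_predictor_ci_covers_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"y": rng.binomial(1, 0.5, 5000), "x": rng.standard_normal(5000)}
        )
        res = fit_logistic(df, "y", ["x"])
        row = res.odds_ratios.iloc[0]
        assert row["ci_lo"] < 1 < row["ci_hi"]

    def test_parameter_recovery_ln2(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(5000)
        y = rng.binomial(1, 1 / (1 + np.exp(-np.log(2) * z)))
        res = fit_logistic(pd.DataFrame({"y": y, "z": z}), "y", ["z"])
        assert 1.9 <= res.odds_ratios.iloc[0]["odds_ratio"] <= 2.1

    def test_lr_chi2_reported_per_predictor(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(800)
        y = rng.binomial(1, 1 / (1 + np.exp(-z)))
        res = fit_logistic(pd.DataFrame({"y": y, "z": z}), "y", ["z"])
        chi2, p = res.lr_chi2["z"]
        assert chi2 > 10 and p < 1e-3

    def test_separation_flagged_and_refit(self):
        df = pd.DataFrame({"y": [0] * 20 + [1] * 20,
                           "x": list(range(20)) + list(range(30, 50))})
        res = fit_logistic(df.astype(float), "y", ["x"])
        assert not res.converged  # separation detected, penalized refit used

    def test_non_binary_outcome_rejected(self):
        df = pd.DataFrame({"y": [0.0, 1.0, 2.0] * 10, "x": np.arange(30.0)})
        with pytest.raises(ValueError):
            fit_logistic(df, "y", ["x"])


class TestForest:
    def test_margins_sum_to_cohort_n(self, scored):
        data, _ = scored
        fd = build_forest(data, "class_aggregation", ["plt", "pct", "uric_acid"])
        for _, row in fd.rows.iterrows():
            assert row[["a", "b", "c", "d"]].sum() == len(data)

    def test_study_outcome_margins(self, scored):
        # outcome split is 126/125 by construction of the median split
        data, _ = scored
        fd = build_forest(data, "class_aggregation", ["plt"])
        row = fd.rows.iloc[0]
        assert row["a"] + row["c"] == 125  # higher-reactivity column
        assert row["b"] + row["d"] == 126

    def test_self_predictor_extreme_and_flagged(self, scored):
        data, _ = scored
        data = data.copy()
        data["self"] = data["cum_aggregation"]
        fd = build_forest(data, "class_aggregation", ["self"])
        row = fd.rows.iloc[0]
        assert row["odds_ratio"] > 100
        assert "extreme" in row["flag"]

    def test_null_predictors_pooled_ci_covers_one(self):
        rng = np.random.default_rng(3)
        n = 2000
        df = pd.DataFrame(
            {
                "class_y": rng.binomial(1, 0.5, n),
                "p1": rng.standard_normal(n),
                "p2": rng.standard_normal(n),
                "p3": rng.standard_normal(n),
            }
        )
        fd = build_forest(df, "class_y", ["p1", "p2", "p3"])
        pooled = fd.pooled["all"]
        assert pooled.ci[0] < 1 < pooled.ci[1]

    def test_constant_predictor_excluded_with_warning(self, scored):
        data, _ = scored
        data = data.copy()
        data["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            fd = build_forest(data, "class_aggregation", ["flat", "plt"])
        assert list(fd.rows["predictor"]) == ["plt"]

    def test_sex_stratification_splits_cohort(self, scored):
        data, _ = scored
        fd = build_forest(data, "class_global", ["plt"], stratify_by_sex=True)
        by = fd.rows.set_index("stratum")
        assert by.loc["men", ["a", "b", "c", "d"]].sum() == 126
        assert by.loc["women", ["a", "b", "c", "d"]].sum() == 125
        assert set(fd.pooled) == {"men", "women"}
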