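#!/usr/bin/env python
"""Risk-factor models: forest data (median-split 2x2 tables, per-predictor
ORs, descriptive Mantel-Haenszel pooled OR, overall and by sex) and the
age/sex-adjusted multiple logistic model with Hosmer-Lemeshow calibration.
Writes forest tables and the logistic OR table."""

from pathlib import Path

from plateletscore.cohort import CohortTable
from plateletscore.risk import build_forest, fit_logistic

OUT = Path("results")
FOREST_PREDICTORS = ["plt", "pct", "p_lcr", "mpv", "wbc", "uric_acid"]
LOGISTIC_PREDICTORS = ["plt", "pct", "p_lcr", "wbc", "uric_acid",
                       "sh_plt", "nh2_plt"]


def main() -> None:
    table = CohortTable.from_csv(OUT / "cohort_scored.csv")
    data = table.data

    for outcome in ("class_aggregation", "class_global"):
        fd = build_forest(data, outcome, FOREST_PREDICTORS)
        fd.to_frame().to_csv(OUT / f"forest_{outcome}.csv", index=False)
        pooled = fd.pooled["all"]
        print(f"{outcome}: pooled MH OR = {pooled.odds_ratio:.3f} "
              f"(95% CI {pooled.ci[0]:.3f}-{pooled.ci[1]:.3f}, p={pooled.p:.3g})")

        fd_sex = build_forest(data, outcome, FOREST_PREDICTORS,
                              stratify_by_sex=True)
        fd_sex.to_frame().to_csv(OUT / f"forest_{outcome}_by_sex.csv", index=False)
        for label, orr in fd_sex.pooled.items():
            print(f"  [{label}] pooled MH OR = {orr.odds_ratio:.3f} "
                  f"(95% CI {orr.ci[0]:.3f}-{orr.ci[1]:.3f})")

    res = fit_logistic(data, "class_global", LOGISTIC_PREDICTORS,
                       adjustment=("age", "sex"))
    res.odds_ratios.to_csv(OUT / "logistic_or.csv", index=False)
    print("\njoint logistic model (age/sex adjusted), per-predictor OR:")
    for _, r in res.odds_ratios.iterrows():
        if r["role"] != "predictor":
            continue
        chi2, _ = res.lr_chi2.get(r["predictor"], (float("nan"), None))
        print(f"  {r['predictor']:<12s} OR={r['odds_ratio']:.3g} "
              f"(95% CI {r['ci_lo']:.3g}-{r['ci_hi']:.3g}), p={r['p']:.2g}, "
              f"LR chi2={chi2:.1f}")
    print(f"Hosmer-Lemeshow p = {res.hl_p:.3f} "
          f"({'calibrated' if res.hl_p > 0.05 else 'miscalibrated'})")


if __name__ == "__main__":
    main()
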