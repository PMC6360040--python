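# plateletscore

Composite platelet-reactivity scoring and multi-stage inference for
population studies of haemostasis in older adults.

Platelet reactivity in a cohort is measured per agonist (arachidonic acid,
collagen, ADP) by impedance aggregometry and by flow cytometry of surface
activation antigens (P-selectin, activated GPIIb/IIIa). These readouts are
skewed and live on incompatible scales, so this package builds the
analysis around a rank-based composite: each readout is normalized with
**van der Waerden normal scores** — the value with mid-rank *r* among *n*
maps to Φ⁻¹(r/(n+1)) — the scores are summed over a named component set
into a **cumulative reactivity score**, and the score is dichotomized at
its sample median into "lower" (≤ Me, rank 0) and "higher" (> Me, rank 1)
reactivity classes. Every downstream classification is therefore invariant
under monotone rescaling of the raw instruments.

Around that construct the package provides the full inferential workflow:

* **synthetic cohort generator** — a Gaussian copula (Spearman targets
  mapped to the latent Pearson scale by ρ_P = 2·sin(πρ_S/6)) with
  clinically parametrized, sex-specific marginals, reproducing the
  published structure of a 251-subject cohort aged 60–65 (125 women,
  126 men) so every stage runs without the undeposited raw data;
* **preprocessing** — Grubbs/Tukey outlier flags, kNN imputation of
  variables missing in < 3% of subjects, and a normality/homoscedasticity
  gate with Box–Cox rescue;
* **associations** — Spearman correlations with percentile-bootstrap CIs
  and jackknife influence diagnostics, sex-stratified Fisher-z pooling,
  assumption-gated two-group tests, permutation-resampled ANCOVA, and the
  Fisher-z sample-size formula n = ((z₁₋α/₂+z_power)/atanh r)² + 3;
* **risk models** — per-predictor odds ratios over median-split 2×2
  tables, fixed-effects Mantel–Haenszel pooled ORs
  (Σaᵢdᵢ/nᵢ)/(Σbᵢcᵢ/nᵢ) with Robins–Breslow–Greenland CIs for forest
  displays (optionally sex-stratified), and multiple logistic regression
  with Hosmer–Lemeshow calibration;
* **multivariate discrimination** — forward-stepwise LDA ranked by
  partial Wilks' λ, canonical correlation analysis with extracted-variance
  and redundancy indices, and a classifier panel (Chebyshev-kNN, linear
  SVM, naive Bayes, a minimal MARS) combined by majority vote ("voting of
  k judges").

See `docs/methods.md` for the statistical details and design choices.

## Worked example

The `analysis/` scripts run the whole study as a narrative; the same steps
in a few lines:

```python
from plateletscore import (
    generate_cohort, study_config, score_cohort, spearman_boosted,
    build_forest, required_n,
)

cohort = generate_cohort(study_config(seed=20240917))
data, scores = score_cohort(cohort.data)

agg = scores["aggregation"]
print(agg.label, agg.class_counts)       # median split of the 251 subjects

r = spearman_boosted(data["uric_acid"], data["cum_aggregation"], seed=1)
print(f"R_s={r.r_s:+.3f}, p={r.p:.2g}, CI={r.ci}")

forest = build_forest(data, "class_aggregation",
                      ["plt", "pct", "p_lcr", "uric_acid"])
print(forest.pooled["all"].odds_ratio)

print(required_n(0.22, alpha=0.01, power=0.90))
```

Running the analysis scripts in order prints, among other things:

```
cumulative platelet reactivity_aggregation: Me=+0.082, lower n=126, higher n=125
design: detecting r=0.22 at alpha=1%, power 90% needs n=301 (~300)
  pct                R_s=+0.392  p=1.2e-10  95% CI [+0.280, +0.496]
  uric_acid          R_s=-0.276  p=9.3e-06  95% CI [-0.394, -0.148]
sex-adjusted (stratified) estimates:
  uric_acid  pooled R_s=-0.170, p=0.0071
class_aggregation: pooled MH OR = 1.634 (95% CI 1.337-1.996, p=1.61e-06)
Hosmer-Lemeshow p = 0.587 (calibrated)
```

Read: at the study size the median split is exactly 126 vs 125; the
Fisher-z design formula reproduces the ~300-subject recruitment target;
plateletcrit associates positively and uric acid negatively with the
cumulative aggregation score (the sex-adjusted uric-acid correlation sits
at −0.170); the forest of median-split morphology/uric-acid predictors
pools to OR ≈ 1.6 for higher reactivity; and the joint logistic model is
well calibrated.

A `plateletscore` CLI wraps the same stages
(`simulate`, `preprocess`, `score`, `associate`, `forest`,
`discriminate`, `run`); try `plateletscore --help`.

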