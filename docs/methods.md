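# Methods

`plateletscore` implements a composite, rank-based workflow for asking
which routinely measured blood variables — morphology, serum biochemistry,
oxidative-stress markers — shape platelet reactivity in older adults, and a
synthetic cohort generator that reproduces the statistical structure the
workflow assumes so every stage is exercisable without access to the
original per-subject data.

## The composite reactivity score

Platelet reactivity is read out per agonist (arachidonic acid, collagen,
ADP) by whole-blood impedance aggregometry (maximal aggregation `Amax`,
area under the curve `AUC`, and the integrative indicator
`(Amax × AUC)/1000`), and by flow cytometry (surface P-selectin/CD62P and
activated GPIIb/IIIa, resting and agonist-stimulated). These readouts live
on different, skewed scales, so the pipeline normalizes each variable with
van der Waerden normal scores: the value with mid-rank *r* among *n* maps
to Φ⁻¹(r/(n+1)). Ties share the average rank and hence a score; a tie-free
column has mean exactly zero and all scores lie strictly inside
(Φ⁻¹(1/(n+1)), Φ⁻¹(n/(n+1))).

Normal scores over a named component set are **summed** (not averaged) into
a cumulative score. Summing was chosen because the published group
contrast of the global score (means about −2.1 and +2.2, SD 3.2) is on the
scale of a sum over roughly five unit-variance components; `cumulate`
accepts `aggregate="mean"` for users who prefer the average. The shipped
component sets are:

| score | components |
|---|---|
| reactivity_aggregation | Amax for AA, COL, ADP |
| activation | resting P-selectin + resting activated GPIIb/IIIa |
| P-selectin expression | stimulated P-selectin (AA, COL) |
| active GPIIb/IIIa expression | stimulated GPIIb/IIIa (AA, COL) |
| reactivity_flow cytometry | all four stimulated antigen readouts |
| global reactivity | 3 Amax at weight 1 + each stimulated antigen as the mean of its AA/COL scores |

The global set is deliberately five *effective* components: the three
aggregometry readouts plus one component per antigen (each the average of
its two stimulated scores, implemented as weight 0.5 on four columns).
This matches the reading "aggregation across three agonists plus the two
antigen expressions" and keeps the score on the published scale.

Each cumulative score is dichotomized at its interpolated (type-7) sample
median: class 0 ("lower reactivity") for values ≤ Me, class 1 ("higher
reactivity") above. For odd *n* with distinct values the split is exact —
at the study size of 251 it always yields 126 vs 125 — and because normal
scores depend only on ranks, the classification is invariant under any
strictly increasing transformation of the raw readouts.

## Synthetic cohort

The generator emulates the study population (251 subjects aged 60–65;
125 women, 126 men) with a Gaussian copula over ~50 panel variables:

* **Marginals** are parametrized the way clinical tables report them.
  Right-skewed laboratory variables use a shifted lognormal back-solved
  from the printed median and quartiles (σ = ln(q₇₅/q₂₅)/(2·z₀.₇₅));
  variables reported as mean ± SD (RBC, P-LCR, uric acid) are normal; age
  is a scaled beta on the recruitment window [60, 65]. Sex-specific
  parameters reproduce the female/male columns of the descriptive table.
  A few panel variables have no published marginals; package defaults were
  fixed once at field-typical values: per-agonist AUC scaled ~10× the
  corresponding Amax medians with the same relative IQR, TAS 1.1
  (0.9; 1.3) mmol/l, TOS 12 (6; 22) µmol/l, thromboxane 120 (70; 200).
  The basophil IQR collapses at the printed precision, so basophils use a
  normal family with SD = IQR/1.349. The female LDL median is not printed;
  the geometric mid-quartile (136.3 mg/dl) is used.
* **Dependence** is specified as a matrix of target Spearman correlations,
  mapped to the Pearson scale of the latent normal by
  ρ_P = 2 sin(π ρ_S/6). Published pairwise correlations (platelet
  morphology vs per-agonist aggregation, uric acid and red-cell indices vs
  ADP response, etc.) are encoded alongside physiological coupling terms
  (RBC–HGB–HCT, PLT–PCT, MPV–PDW–P-LCR, cross-agonist reactivity). If the
  assembled matrix is jointly infeasible it is repaired by
  nearest-positive-definite projection (eigenvalue clipping, unit-diagonal
  rescale); a non-repairable matrix fails loudly naming the offending
  entries.
* **Missingness** is MCAR, capped at 3% per variable (the imputation
  contract), never touching identity columns or age.

Because the marginal transforms are strictly monotone *within* each sex,
the copula targets are exact for the within-sex (sex-adjusted) rank
correlations; the pooled two-sex correlation additionally carries the
component mediated by sex differences in the marginals (e.g. uric acid is
higher and aggregation lower in men). This mirrors how the reported
correlations were sex-adjusted. Tests of copula fidelity therefore use
sex-homogeneous configurations.

What the generator does **not** emulate: higher-order dependence beyond
pairwise rank structure, measurement error models, any
missingness-by-cause mechanism, or the raw aggregometry/cytometry curves
(only their summary readouts). Passing tests demonstrate that the
*pipeline machinery* is correct and calibrated under the study's assumed
structure, not that the original cohort's printed estimates are recovered
— those depend on data that were never deposited.

## Preprocessing

* **Outliers**: Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR) or two-sided
  iterative Grubbs at α = 0.05 with at most 2 removals per variable
  (conventional defaults; both configurable). Outliers are flagged and
  reported, never silently dropped — how the original analysis handled
  them is unstated, so the pipeline defaults to flag-only.
* **Imputation**: single-pass kNN (k = 5 default). Distances are
  Euclidean over standardized columns shared complete between recipient
  and donor, scaled per-column so recipients with different missingness
  patterns are comparable; each missing cell becomes the mean of its k
  nearest complete donors. Variables with ≥ 3% missingness are skipped and
  reported. Re-running on a complete table is the identity.
* **Assumption gate**: Shapiro–Wilk per group and Brown–Forsythe (Levene
  with median centring) across groups at α = 0.05. On violation, a Box–Cox
  transform (ML λ, positivity shift 1 − min(x) when min ≤ 0) is applied
  and the assumptions re-checked; persistent violation routes to the
  nonparametric branch.

## Association stage

* `spearman_boosted`: Spearman via the mid-rank Pearson formula; two-sided
  p by the t approximation, replaced by exact permutation enumeration for
  n ≤ 8 (40 320 permutations; enumerating up to n = 10 would cost 3.6 M
  Python-level iterations for a diagnostic no analysis path exercises);
  percentile-bootstrap CI (default B = 2000); leave-one-out jackknife
  range with an influence flag when any single deletion flips the sign or
  moves the estimate by more than 0.1. The "resampling-validated"
  correlation is thus the plain estimator plus diagnostics — resampling
  never modifies the point estimate.
* Sex adjustment of simple correlations: per-stratum Spearman pooled on
  the Fisher-z scale with weights n_k − 3.
* `ancova_boosted`: the group-effect F from the linear model
  `y ~ covariates + group`, referred to its permutation null (group labels
  permuted, covariates fixed to subjects; p = fraction of B resamples with
  F* ≥ F_obs, add-one smoothed). B = 10 000 by default for group
  contrasts, vectorized for the binary-group case. At least 1000
  iterations are enforced.
* `required_n`: Fisher-z closed form n = ((z₁₋α/₂ + z_power)/atanh r)² + 3,
  returned as both ceiling and rounded-to-ten. At r = 0.22, α = 0.01,
  power 0.90 it gives 301 (~300), reproducing the study's design target.
* No multiplicity correction by default (the source analyses report
  unadjusted p-values); an optional Benjamini–Hochberg column is available.

## Risk-factor stage

Explanatory variables are dichotomized at their own medians by the same
rule as the outcome, cross-tabulated against the outcome class, and
summarized as per-predictor odds ratios (Woolf log-scale CI;
Haldane–Anscombe 0.5 correction on zero cells) plus a fixed-effects
Mantel–Haenszel pooled OR with the Robins–Breslow–Greenland variance. The
pooled OR across *different predictors* is labelled descriptive in the
output: the predictors are correlated within subjects, so the independence
assumption behind fixed-effects pooling is knowingly violated; the number
summarizes a forest display, it is not a meta-analytic estimate. When one
side's cross-products vanish in every stratum (e.g. a perfectly separating
predictor), zero-containing strata are continuity-corrected and the result
flagged.

Multiple logistic regression (statsmodels ML fit) reports per-predictor
exp(β) with Wald 95% CIs, a likelihood-ratio χ² for dropping each
predictor (the χ² attached to individual predictors in the source is not
named; it is reported here under the explicit LR label), and
Hosmer–Lemeshow calibration over g = 10 equal-size groups of predicted
risk (df = g − 2). Complete separation is flagged and refit with an L2
penalty.

## Multivariate stage

* **Stepwise LDA**: forward selection maximizing the drop in Wilks' Λ
  (det W / det T), with partial Λ = Λ(model)/Λ(model − variable) and the
  F approximation F = (df₂/df₁)(1 − Λp)/Λp, df₁ = g − 1,
  df₂ = n − g − p_in. Thresholds: p-to-enter 0.05, p-to-remove 0.10.
  Singular within-group scatter is ridge-stabilized (1e-8 of the mean
  total variance) with a warning.
* **Canonical analysis**: SVD of the whitened cross-correlation matrix
  R₁₁^{-1/2} R₁₂ R₂₂^{-1/2}; structure loadings are correlations between
  original variables and canonical variates. Extracted variance per set
  per variate is the mean squared loading; redundancy multiplies it by the
  paired variate's squared canonical correlation. Both are summed over the
  variates with Bartlett χ² p < 0.05 (at least one), which is why extracted
  variance can be well below 100%. "Best contributors" are variables with
  |loading| ≥ 0.3 on the first variate — a reporting convention, stated in
  the output.
* **Classifier panel**: kNN (Chebyshev distance by default, k chosen by
  leave-one-out over {3, 5, 7, 9}), linear SVM (C = 1), Gaussian naive
  Bayes, and a deliberately minimal MARS classifier (additive hinge basis,
  knots at feature quantiles, greedy forward selection capped at 10 terms,
  GCV backward pruning that never empties the basis, logistic refit).
  All judges are evaluated under leave-one-out by default (whether the
  original accuracies were in-sample is unstated; `evaluation="insample"`
  is available). Consensus is per-subject majority vote; a tied vote
  abstains and is counted incorrect, and the rule is recorded in the
  output. Reproducing the original panel accuracies (90.2%, 89.3%) is
  explicitly out of scope — they depend on the undeposited cohort.

## Numerical choices and degenerate inputs

* Type-7 (interpolated) medians throughout, matching NumPy's default.
* Constant score vectors dichotomize to all-class-0 with a warning;
  constant predictors are excluded from forests with a warning; constant
  vectors are rejected by the correlation and Grubbs routines with
  explicit messages.
* All resampling is seeded; seeds are recorded in every result object and
  output table. Bootstrap resamples that produce degenerate (constant)
  columns are dropped from the percentile computation.
* Copula uniforms are clipped to (1e-12, 1 − 1e-12) before quantile
  transformation.

## Problem sizes in the test and acceptance suites

Monte-Carlo suites run at the sizes a reviewer can re-run on one CPU:
correlation recovery uses 1000 replicate cohorts at n = 251; CI coverage
1000 replicates with B = 1000; ANCOVA null calibration 2000 replicates
with B = 2000 at n = 100; Hosmer–Lemeshow calibration 1000 replicates at
n = 500; logistic OR recovery averages 50 replicates at n = 5000. The
acceptance script uses 400-replicate versions of the same measurements.

## Known limitations

* The Gaussian copula cannot represent tail dependence or nonmonotone
  relations between panel variables.
* The descriptive pooled OR across correlated predictors has no sampling
  interpretation; its CI is conditional on the (violated) independence
  assumption and should be read as a display summary.
* kNN imputation underestimates variance relative to multiple imputation;
  this matches the single-pass design of the emulated workflow (no MICE).
* The MARS judge is minimal by design (degree 1, ≤ 10 terms) and is not a
  general MARS implementation.
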