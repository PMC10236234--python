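# Methods

## Synthetic cohort model

Everything downstream is exercised against a generator that emulates the
statistical structure of a multi-site brain-aging cohort study. For subject
*i* on ROI *v*:

    y_iv = b_v + f_v(age_eff,i) + β_sex,v·male_i + β_icv,v·(ICV_i − ICV₀)
           [+ c_v] + s_{k(i),v} + σ_{k(i),v}·ε_iv ,     ε_iv ~ N(0, noise_sd²)

- **Baselines** `b_v ~ U(4000, 12000)` mm³ — the range of mid-sized
  gray-matter parcels.
- **Age trend** `f_v(a) = −k_v·max(a − 30, 0)²`: flat until a plateau age of
  30, then a monotone quadratic decline. Decline rates are calibrated so the
  per-year loss at age 60 is 10–30 mm³ (≈0.1–0.5 %/yr), the order reported
  for adult gray-matter atrophy. A configurable fraction of ROIs
  (`affected_roi_fraction`, default 0.6) is age-sensitive; the rest are flat.
- **Accelerated aging** is injected as an *age shift*: study-arm subjects
  are generated at `age + aging_offset_years` on age-sensitive ROIs only.
  Because the injection is in years, the years-equivalent statistic has an
  exact ground truth, which is what the end-to-end recovery checks exploit.
- **AD signature**: the last `ad_signature_fraction` (default 0.2) of ROIs,
  disjoint from the age-sensitive set, lose `ad_effect_sd` × `noise_sd` mm³
  in AD-labeled reference subjects. Using the residual noise SD as the unit
  makes the injected standardized effect exactly recoverable from adjusted
  means. Keeping the two ROI sets disjoint gives the clean dissociation the
  indices are designed to exhibit; real AD-signature regions also age, so
  this is an idealization.
- **Scanner effects**: per scanner × ROI, an additive shift
  `~N(0, site_shift_sd²)` (default 80 mm³) and a multiplicative noise scale
  `exp(N(0, site_scale_sd²))` (default 0.15 log units). Scanner assignment
  is a balanced random permutation per arm so both groups appear on every
  scanner and group and scanner effects are separable.
- **Cohort offset**: study and control arms additionally carry a per-ROI
  shift `c_v ~ N(0, cohort_shift_sd²)` (default 50 mm³) relative to the
  reference cohort's space — the between-consortium offset that the second
  harmonization step removes.
- **Demographics**: study/control ages uniform on 44–74 (the study arm's
  range), reference ages uniform on 20–90 — a lifespan reference is needed
  for the brain-age regression to learn the age trend well beyond the study
  range. Sex is balanced; ICV is sex-dependent (males ≈1.55·10⁶ mm³,
  females ≈1.35·10⁶); education ~N(15.6, 1.9) years (controls slightly
  higher, N(16.2, 1.5)).
- **Cohort sizes** default to the emulated design: 416 study, 99 control,
  24 scanners, 145 ROIs, 221 AD-pattern reference cases. The reference
  cohort defaults to 600 (the emulated consortium had thousands; 600 keeps
  default runs in minutes while leaving the brain-age model well determined).
- **Risk histories**: roughly annual visits with ±50 % jitter from baseline
  to 32 years of follow-up; quantitative factors (HbA1c-, BMI-, blood-
  pressure-like) follow a mean-reverting walk (AR(1), φ=0.7) around a
  subject-level mean; severe-hypoglycemia counts are Poisson with a
  susceptible-fraction mixture; binary complications are per-visit reports.
  Controls get a single cross-sectional visit at the study end.

Structural parameters (baselines, decline rates, covariate coefficients,
scanner effects) come from a generator seeded by a fixed internal constant,
so configs that differ only in `seed` share identical deterministic
components and differ only in subject-level draws. All randomness flows
through explicitly passed seeded generators; identical config + seed is
bit-reproducible.

What the generator does **not** emulate: spatial correlation between
neighboring ROIs, heavy-tailed or skewed volume distributions, age-by-sex
interactions, scanner upgrades over time, missing visits, and attrition.
Passing tests therefore demonstrate correctness of the pipeline's
statistical machinery under its stated model, not robustness to every
feature of real imaging data.

## ComBat-GAM harmonization

Per ROI the covariate model is fitted pooled across batches:

    y_iv = α_v + f_v(age_i) + x_i'β_v + σ_v(γ_{k(i),v} + δ_{k(i),v} ε_iv)

- **Age trend**: cubic B-spline with 10 basis functions (interior knots at
  age quantiles), one column dropped to break the partition-of-unity
  collinearity with the batch intercepts, columns centered. A
  second-difference penalty on the spline coefficients is chosen per ROI by
  generalized cross-validation over λ ∈ 10^{−2..8} (11 grid points); since
  the design is shared across ROIs the GCV path is vectorized. Ages outside
  the fitted range are linearly extrapolated (with a logged warning).
- **Linear covariates**: sex (male = 1), ICV (standardized by fit-time
  mean/SD), diagnosis one-hot with the control level as reference.
  Diagnosis is coded as *clinical* status (controls from either cohort share
  one level) — otherwise diagnosis would be exactly collinear with the
  cohort batch in the second step.
- **Standardization**: the grand intercept is the batch-size-weighted mean
  of the per-batch intercepts (or the reference batch's own intercept in
  reference mode); σ_v² is the pooled mean squared residual (reference-batch
  residuals only, in reference mode).
- **Empirical Bayes**: per batch, the per-ROI location means and scale
  variances of the standardized residuals are shrunk with a normal prior on
  γ and an inverse-gamma prior on δ², prior moments estimated across ROIs
  within the batch, and the coupled posterior-mean equations iterated to a
  relative tolerance of 10⁻⁴ (max 100 iterations; non-convergence raises an
  error reporting the last change).
- **Reference-batch mode**: γ*, δ* are expressed relative to the reference
  batch, whose rows are returned bit-identical (they are copied through —
  the algebraic round trip alone would differ at float rounding).
- **Two-step design**: step 1 removes scanner effects within the study data
  (covariates age, sex, ICV, diagnosis); step 2 treats pooled-study vs
  reference as two batches (covariates age, sex, diagnosis — the quoted
  roster for the consortium-level step omits ICV, and that roster is kept)
  with the reference cohort as reference batch. Whether the consortium
  analysis held its reference fixed or re-estimated jointly is not
  documented; both modes exist here (`reference_batch_mode`), fixed
  reference being the default because the downstream index models live in
  the reference space.
- Degenerate inputs: batches need ≥3 subjects (scale estimation); a single
  batch yields an identity model; rank-deficient designs raise an error
  naming the collinear columns (pivoted QR); subjects with missing
  covariates are dropped with a logged count.

A note on post-harmonization batch testing: a one-way scanner test run on
the same data the correction was estimated from is conservative by
construction (batch means are over-equalized), while corrections estimated
from batches no larger than the test sample add estimation noise and
inflate the test. The null-calibration property is therefore demonstrated
in the regime where it is well posed — a model fitted on a large draw and
applied to a smaller held-out draw — where the p-value distribution is
uniform (KS check in the test suite).

## SPARE indices

- **SPARE-BA**: linear ε-insensitive SVR (liblinear; ε = 0.1 years) on
  standardized ROI volumes of healthy controls. C is selected by inner
  5-fold CV over 10^{−3..3}; held-out MAE and age–prediction correlation
  come from an outer 5-fold CV and are stored in `training_meta` together
  with the selected C and seed. The liblinear iteration cap (3000) may stop
  large-C grid points early; those fits lose the CV selection, which is the
  intended behavior.
- **SPARE-AD**: linear soft-margin SVM (hinge-loss liblinear), AD coded +1
  and controls −1, C selected on balanced accuracy, outer-CV balanced
  accuracy recorded. The signed decision value is the score. Decision-value
  units are model-specific (they scale with the margin), so cross-model
  comparisons are made in score-SD units.
- Only the linear kernel is implemented; a nonlinear kernel would preclude
  the portable weight-vector serialization and adds nothing at ROI-level
  dimensionality. Feature standardization constants are computed on the
  training data only and frozen into the model. An optional regression-to-
  the-mean bias correction of predicted age on age (slope/intercept
  inversion) is available but off by default.
- Scoring is a deterministic linear map with a strict ROI-roster check.

## Longitudinal summaries

`time_weighted_mean` implements Σwᵢvᵢ/Σwᵢ with wᵢ = tᵢ − tᵢ₋₁ and t₀ = 0.
Two boundary rules were genuinely open and are fixed as follows: a baseline
visit at t = 0 has an undefined "interval since the last measurement" and
gets zero weight (unless it is the only visit, whose value is returned),
and the window end beyond the last visit does *not* extend the last value's
weight — the rule weights elapsed intervals between measurements only. A
`carry_forward` flag provides the alternative terminal-weight behavior.
Ever-event flags count any truthy report at or before the window end;
cumulative severe-hypoglycemia counts are binned 0 / 1–5 / >5.

## Association analyses

- Group differences in the indices use linear mixed models with a random
  intercept per scanner (structure unspecified in the emulated design;
  a random intercept is the minimal choice), falling back to OLS with a
  logged warning when only one scanner is present. Covariate, regional and
  cognition scans use OLS with scanner fixed effects.
- The years-equivalent gap is β_group/β_age from one mixed model of the
  index on group, age and ICV; the SE is first-order delta method including
  the coefficient covariance. β_age ≤ 0 raises an error — the statistic is
  undefined when the brain-age model carries no age signal.
- Backward elimination refits after every single removal; ties in p are
  broken toward the larger p then lexicographic name for determinism.
  After the p < .10 loop, candidates at p ≥ .05 are dropped and the model
  refitted once. Forced covariates (age, sex, scanner) are never removed.
  Note an inherent bound: with three null candidates the probability that
  *all* are dropped is at most (1 − .05)³ ≈ 0.86 under the retention rule
  itself, so elimination quality is quantified per covariate (the ~95 %
  per-null drop rate and the strong-candidate retention rate), not by the
  joint all-dropped event.
- Regional scans fit all ROIs at once on the shared design (one pinv);
  the standardized effect size is β divided by the ROI's residual SD (no
  standard definition exists for published "effect sizes"; this is the
  package's). Benjamini–Hochberg q-values are computed by a hand
  implementation (q_i = min_{p_j ≥ p_i} m·p_j/rank_j, stable-sort tie
  handling, clipped at 1) and cross-checked against
  `statsmodels.multipletests` in the tests. FDR is applied within one scan
  across ROIs only, never across outcome families.
- Cognition: per-test z-scores against supplied reference means/SDs,
  sign-flipped for tests where higher raw = worse (timed tests; configurable
  per test), unweighted domain averages, mean-of-available for partially
  missing subjects (logged), NaN when all tests are missing. Domain models
  adjust for age, sex, education and scanner. All p-values are two-sided.

## Problem sizes in the checked runs

The end-to-end recovery benchmark uses 20 replicates of 400 study + 100
control + 500 reference subjects, 100 ROIs, 10 scanners; the batch-effect
injection check uses 600 subjects on 2 scanners and 40 ROIs; calibration
suites use 1000 fits (type-I error), 1000 random vectors (FDR) and 100 runs
(elimination). These sizes leave every estimate's Monte-Carlo error well
inside the asserted tolerances while keeping a full run in minutes on one
CPU.

## Known limitations

- Voxel-level and longitudinal (repeated-scan) harmonization are out of
  scope; so is nonparametric empirical Bayes.
- The generator's idealizations listed above; in particular, flat
  AD-signature ROIs make the dissociation cleaner than real data would.
- SVM decision values are not calibrated probabilities; SPARE-AD scores are
  comparable within one model only.
- The pipeline models cross-sectional outcomes; no survival, mediation or
  causal analyses.
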