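# Methods

This note documents the models, conventions and numerical choices behind
`carotid_gsm`, in the spirit of a statistical methods appendix. Everything
stated here is computed by the package's tests or by
`scripts/acceptance.py`; no empirical claim below goes beyond what those
runs produce.

## 1. Plaque echogenicity (GSM)

### Measurement model

A carotid plaque on B-mode ultrasound is summarized by its gray-scale
median (GSM) after a two-point brightness normalization that makes scans
comparable across devices and gain settings. Let `L` be the median raw
gray value of a region marked inside the vessel lumen (blood, ideally
anechoic) and `A` the median of a region on the adventitia (the
brightest arterial wall layer). Each raw pixel `g` is mapped to

    g' = clip( round( 190 * (g - L) / (A - L) ), 0, 255 )

so lumen-level pixels land at 0 and adventitia-level pixels at 190 — the
anchor values used throughout the GSM literature. `A <= L` is rejected
as a non-discriminating annotation. Rounding is half-up; pixels are
8-bit before and after.

Conventions we had to fix because the original annotation tooling is a
GUI whose geometry rules are not published:

* 0-based, row-major pixel grid, origin top-left; the pixel at
  (row r, col c) has center (x, y) = (c + 0.5, r + 0.5).
* A pixel belongs to a polygon iff its center is inside under the
  even-odd (crossing-number) rule. This is well defined for concave and
  self-intersecting outlines and is verified against an exhaustive
  per-pixel oracle in the tests.
* Reference summary for `L` and `A` is the region *median* — robust to
  a few stray pixels in a hand-drawn marker.
* Noise reduction is a single-pass 3×3 median filter with reflected
  borders, applied to the raw frame *before* normalization (the order
  is a flag; reference medians are robust to it either way).
* Cropping to the plaque bounding box is bookkeeping only: statistics
  are mask-based and unaffected by it.

Per plaque segmentation we report min / max / mean / median of the
normalized pixels under the plaque mask (median of an even count is the
midpoint of the central order statistics, i.e. the NumPy convention).
The participant-level outcome is the flat arithmetic mean over all
plaque × observer measurements; both observers' segmentations of the
same plaque count as separate measurements. A per-plaque-average-first
mode exists behind `per_plaque_first=True` for sensitivity analyses.

### Interobserver agreement

Agreement on a reproducible 5% participant subsample (ceil(0.05·n),
simple random sample under a seed) is quantified by the two-way
random-effects, single-measurement, absolute-agreement ICC — ICC(2,1),
computed via `pingouin` and cross-checked in the tests against the
hand-evaluated ANOVA formula — plus the mean paired difference and
Bland–Altman 95% limits of agreement. Pairs whose difference deviates
from the mean difference by more than k·SD (default k = 3) are flagged
for remeasurement. We center the rule on the mean difference (the
Bland–Altman convention) rather than on zero: an uncentered rule
degenerates whenever a systematic offset between observers dominates,
flagging everything or nothing.

## 2. Dietary adherence scores

* **MEDAS**: 14 binary adherence items; total 0–14; categories
  0–3 / 4 / 5 / 6+. A missing item scores 0 and is flagged, so a partial
  questionnaire can only lower the score (conservative); for regression
  use, fully missing scores propagate as missing into imputation
  instead of being zeroed.
* **DASH** (Folsom-style): 10 components — 7 food groups (grains,
  vegetables, fruits, dairy, meat/poultry/fish, nuts/seeds/legumes,
  sweets) and 3 nutrients (saturated fat, total fat as % of energy,
  sodium). Each scores 1 at target, 0.5 at an intermediate threshold,
  else 0; total 0–10 in 0.5 steps; categories 0–3.5 / 3.6–4.5 /
  4.6–5.0 / 5.1+ (the apparent gaps, e.g. (4.5, 4.6), are unattainable
  with 0.5-step totals — asserted in the tests). Component thresholds
  are configuration (`data/dash_thresholds.yaml`), shipped with
  provisional defaults following DASH guideline targets (intermediate =
  halfway for foods, a relaxed bound for nutrients), because the exact
  instrument cutoffs are questionnaire-specific.
* **FFQ aggregation** is linear: each profile field is
  Σ_item frequency · portion · per-gram coefficient from a composition
  table. The composition table used in tests is a tiny unit-normalized
  synthetic fixture so worked examples are closed-form.
* **Supplements**: six tracked flags (multivitamins, multiminerals,
  calcium, magnesium, vitamin B, folate; used ≥1 month in the last
  year). `any_supplement` is a three-valued OR so that missing
  questionnaire blocks propagate to imputation.

Regression exposure codings: linear GSM models use the four diet
categories with the lowest as reference (MEDAS < 4, DASH < 3.6) and
each supplement against no intake. Logistic plaque models collapse the
four categories to low / medium / high — MEDAS: 0–3 / {4, 5} / 6+;
DASH: 0–3.5 / {3.6–4.5, 4.6–5.0} / 5.1+ — with medium as reference.
The three-group cut is a declared convention; the synthetic generator
uses the same one, so recovery checks are internally consistent.

## 3. Cohort models

* **Education**: ISCED 2011 levels mapped 0–2 → low, 3–4 → medium,
  5–8 → high (declared cut).
* **Linear GSM models** (per sex, plaque sub-cohort): OLS of GSM on the
  exposure plus age, SES index, no-sports, BMI, smoking, energy intake,
  dyslipidemia, hypertension, diabetes, myocardial infarction, heart
  failure, atrial fibrillation, stroke/TIA history, PAD, eGFR and the
  four medication classes. Rank-deficient designs raise an error
  listing aliased terms.
* **Logistic plaque models** (full cohort): plaque presence on the
  exposure plus age, sex, education, BMI, diabetes, hypertension,
  hyperlipidemia, smoking, heart failure, atrial fibrillation,
  myocardial infarction, stroke and no-sports. ORs are exponentiated
  Wald estimates. Separation and single-class outcomes raise specific
  errors. Both imputation-pooled and complete-case modes exist; on a
  2×2 design with no covariates the MLE equals the cross-product odds
  ratio, which the tests assert.
* **Descriptives**: median (q1, q3) for continuous variables (rank-sum
  test between sexes), n (%) for categorical (chi-squared), NA counts
  per variable. Percentages use the full group size as denominator,
  with missing rows counted — the convention of the descriptive tables
  this pipeline mirrors.
* No multiple-comparison adjustment is applied anywhere; α = 0.05,
  two-sided, Wald CIs on the estimation scale (symmetric for betas,
  exponentiated for ORs).

### Multiple imputation

`mice_impute` is a chained-equations engine: m = 20 copies, 10 sweeps
each by default. Families per variable type: type-1 predictive mean
matching (5 donors, posterior parameter draw, candidate matching on
predicted means) for numeric; logistic regression with a large-sample
posterior draw of the coefficients for binary; multinomial logistic
(L-BFGS on the softmax likelihood) for categorical. Every variable is
regressed on all others (one-hot, standardized, intercept; constant
columns dropped), chains are initialized from observed marginals, and
variables are visited in order of increasing missingness. Numerical
safeguards: a 1e-6 ridge on all normal equations, linear predictors
clipped at ±30, single-observed-class variables fall back to marginal
draws. Known approximation: the multinomial step draws classes from
the ML fit's predicted probabilities without a parameter draw, which
slightly understates between-imputation variance for categorical
variables; PMM and the logistic step are proper.

**Rubin's rules**: pooled estimate Q̄ = mean of per-imputation
estimates, within-variance W̄ = mean of squared SEs, between-variance
B = sample variance of estimates, total T = W̄ + (1 + 1/m)·B (held to
machine precision in the tests), Barnard–Rubin small-sample degrees of
freedom when the complete-data sample size is known, t-based CIs and
p-values. With zero missingness the pooled fit equals the single
complete-data fit exactly.

## 4. Synthetic-data generator

### Images

Frames are 128×128 by default: a dark lumen band (raw mean 25), a
bright adventitia band (raw mean 215), mid-gray tissue (90) and an
elliptical plaque outlined by a 40-gon. The plaque's raw level is
chosen so its *post-normalization* mean hits the requested target
(56.5 by default); fractional targets are realized by deterministic
dithering between adjacent gray levels, and the ground truth records
the achieved mean exactly, so at σ = 0 the measured mean equals the
truth bit-for-bit. With the default 25/215 bands the normalization
scale factor is exactly 1, which keeps quantization from biasing the
noiseless path. Noise is additive Gaussian (σ = 8 default) with 8-bit
rounding/clipping; reference regions are rectangles with odd pixel
counts per side so their medians are actual pixel values even under
noise. Default plaque area ≈ 2,000 px, so the Monte-Carlo error of the
plaque mean at σ = 8 is ≈ 0.18 gray units.

### Cohorts

`generate_cohort` draws, per participant: sex (51% female), age
uniform on [45, 75), education (15/55/30), BMI ~ N(26.5, 4.5²) clipped,
binary risk factors and medications at declared prevalences, per-sex
energy intake (lognormal), SES index and eGFR (normal) matched to the
published per-sex median/IQR, per-sex MEDAS and DASH category
distributions, and supplement flags. Supplement flags are drawn
conditionally on the any-supplement flag at their target ratios (the
questionnaire also covers untracked preparations, so any-use may be
true with all tracked flags false).

Plaque presence is Bernoulli(logit⁻¹(β₀ + Xβ)). The diet and
supplement coefficients are the published adjusted ORs (high/low MEDAS
1.07/0.86, high/low DASH 1.18/0.95, any supplement 0.96); the
remaining risk-factor ORs (male 1.8, age 1.08/yr, low/high education
1.3/0.9, BMI 1.02/unit, hypertension 1.6, hyperlipidemia 1.5, smoking
1.7, diabetes 1.2, MI 1.2, heart failure 1.1, stroke 1.1, AF 1.0,
no-sports 1.1) are declared plausible values with the published
significant directions, since only directions — not magnitudes — are
available for them. All defaults live in one YAML
(`data/cohort_defaults.yaml`).

**Selection-consistent calibration.** The descriptive cells the
generator encodes (diet categories, supplement use) describe the
*plaque-positive sub-cohort*, while the generator draws covariates
before the plaque outcome — and diet/supplement terms sit in the
plaque model, so conditioning on plaque presence tilts their
distribution. `calibrate_generator` therefore solves, on a fixed-seed
draw of 200,000 covariate vectors, for the intercept (marginal
prevalence 0.2163) *and* pre-selection per-sex probabilities of the
MEDAS/DASH categories and the any-supplement flag such that the
conditional-on-plaque distributions equal the specified values, by
iterative importance reweighting (converges to < 1e-7 in a few dozen
iterations; result cached per specification). Tracked supplement flags
are conditionally independent of plaque presence given any-use, so
their conditional rates follow automatically. Only the cells named as
calibration targets are matched conditionally; comorbidity prevalences
are specified marginally.

GSM for plaque-positive rows is a per-sex shifted gamma fitted to the
published median/IQR (men 56.50, IQR 46.00–68.50; women 55.80, IQR
44.25–70.33) by solving for the shape whose quartile asymmetry matches,
then scale and location — a right-skewed model consistent with the
published distribution shape — plus the effect terms: +9.12 GSM units
for folate use in men, all other diet/supplement and covariate effects
zero (the published point estimates are null). Values are clipped to
[0, 255].

**Missingness.** `inject_missingness` masks cells MCAR or MAR-on-sex
(per-sex rates, defaults taken from the published per-sex NA counts;
SES ≈ 53/71%, PAD ≈ 52/54%, FFQ block ≈ 11%, supplements ≈ 8%, etc.).
Variables from one questionnaire block (FFQ-derived, supplements,
medications) are masked jointly. The pre-masking table is returned as
the truth record. Note the printed percentages this pipeline
reproduces use the full group as denominator, so e.g. a true
conditional any-supplement rate of 47.7% among women appears as 43.8%
after ~8% of the block is missing — the generator encodes the
observed-data rates and the acceptance script reports the printed-style
percentage.

### What the generator does and does not emulate

It reproduces marginal prevalences, the named conditional cells, the
declared effect sizes, MAR missingness and the GSM outcome
distribution. It does **not** emulate: speckle physics or real plaque
texture; correlations among risk factors beyond the declared links
(age/sex/education/comorbidities enter the plaque model but are drawn
independently of each other); item-level FFQ responses (diet categories
are drawn directly); intra-participant correlation of multiple plaques.
Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the declared data-generating process, not
robustness to real-world confounding structures.

## 5. Problem sizes and randomness

Recovery checks run at n = 100,000 (coefficient recovery through the
full missingness + MICE + pooling path for the folate effect; logistic
recovery for the DASH-high OR), calibration checks at n = 10,000–50,000,
and CI coverage at n = 5,000 over 500 seeded replicates (93–97%
acceptance band; the Monte-Carlo SE of the coverage estimate at 500
replicates is ≈ 1%). Every stochastic operation takes an explicit seed
(NumPy `default_rng`); `scripts/acceptance.py` derives all of its seeds
from the single `--seed` argument via `SeedSequence`. The acceptance
script's full run is dominated by the m = 20 × 10-iteration imputation
of the ~21,600-row plaque sub-cohort.

## 6. Known limitations

* DASH component thresholds are provisional defaults, not instrument
  cutoffs; swap the YAML for a specific questionnaire.
* The multinomial imputation step is not fully proper (see above).
* The SES index is consumed as an opaque numeric; no construction.
* Logistic plaque models default to pooled-over-imputations when given
  an imputation set; complete-case is a flag, not an inference switch.
* No DICOM ingestion (PNG only), no cIMT measurement, no
  juxtaluminal-black-area analysis, no causal claims.
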