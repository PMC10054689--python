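# Default synthetic-cohort specification.
#
# The defaults encode the study conditions of a population-based
# middle-aged German cohort (10,000 participants, ages 45-74) with
# carotid ultrasound: per-sex diet-score category distributions,
# supplement-use prevalences and missing-data rates are the observed
# rates of the plaque sub-cohort (count / non-missing n), the plaque
# model encodes the published adjusted odds ratios for its prevalence
# drivers, and the GSM outcome model is a right-skewed shifted gamma
# matched to the published per-sex median and IQR.  Risk-factor odds
# ratios not printed in the source tables are declared plausible values
# (see docs/methods.md).
n: 10000
female_frac: 0.51

age: {min: 45.0, max: 75.0}

education_probs: {low: 0.15, medium: 0.55, high: 0.30}

bmi: {mean: 26.5, sd: 4.5, min: 16.0, max: 50.0}

binary_prevalence:
  smoking: 0.20
  no_sports: 0.25
  diabetes: 0.08
  hypertension: 0.55
  hyperlipidemia: 0.25
  heart_failure: 0.04
  atrial_fibrillation: 0.05
  prior_mi: 0.03
  prior_stroke_tia: 0.03
  pad: 0.10
  lipid_lowering: 0.18
  antihypertensives: 0.35
  antidiabetics: 0.06
  antiplatelets: 0.15

# per-sex continuous distributions matched to median (q1, q3)
energy_kcal:
  male: {median: 2311.52, q1: 1853.48, q3: 2837.52, family: lognormal}
  female: {median: 1729.92, q1: 1419.01, q3: 2101.23, family: lognormal}
ses:
  male: {median: 13.30, q1: 10.30, q3: 16.70, family: normal}
  female: {median: 11.40, q1: 9.40, q3: 14.20, family: normal}
egfr:
  male: {median: 88.90, q1: 81.20, q3: 94.60, family: normal}
  female: {median: 84.80, q1: 76.30, q3: 90.30, family: normal}

# category order: ["0-3", "4", "5", "6+"]
medas_probs:
  male: [0.41182, 0.24727, 0.15909, 0.18182]
  female: [0.15018, 0.20391, 0.22100, 0.42491]
# category order: ["0-3.5", "3.6-4.5", "4.6-5.0", "5.1+"]
dash_probs:
  male: [0.35909, 0.34273, 0.13818, 0.16000]
  female: [0.11478, 0.32479, 0.21123, 0.34920]

supplements:
  any: {male: 0.30823, female: 0.47749}
  flags:
    multivitamins: {male: 0.08406, female: 0.08412}
    multiminerals: {male: 0.06830, female: 0.12085}
    calcium: {male: 0.05954, female: 0.06991}
    magnesium: {male: 0.15674, female: 0.24052}
    vitamin_B: {male: 0.03940, female: 0.07701}
    folate: {male: 0.02627, female: 0.05450}

plaque_model:
  target_prevalence: 0.2163
  centers: {age: 60.0, bmi: 26.5}
  odds_ratios:
    male_sex: 1.8
    age_per_year: 1.08
    education_low: 1.3
    education_high: 0.9
    bmi_per_unit: 1.02
    diabetes: 1.2
    hypertension: 1.6
    hyperlipidemia: 1.5
    smoking: 1.7
    heart_failure: 1.1
    atrial_fibrillation: 1.0
    prior_mi: 1.2
    prior_stroke_tia: 1.1
    no_sports: 1.1
    medas_high: 1.07
    medas_low: 0.86
    dash_high: 1.18
    dash_low: 0.95
    any_supplement: 0.96

gsm_model:
  male: {median: 56.50, q1: 46.00, q3: 68.50}
  female: {median: 55.80, q1: 44.25, q3: 70.33}
  effects:
    male: {folate: 9.12}
    female: {}

missingness:
  mechanism: mar_sex
  blocks:
    ffq: [energy_kcal, medas_category, dash_category]
    supplements: [any_supplement, multivitamins, multiminerals, calcium,
                  magnesium, vitamin_B, folate]
    medications: [lipid_lowering, antihypertensives, antidiabetics, antiplatelets]
  rates:
    ses: {male: 0.526, female: 0.710}
    bmi: {male: 0.054, female: 0.068}
    smoking: {male: 0.004, female: 0.007}
    no_sports: {male: 0.081, female: 0.087}
    ffq: {male: 0.114, female: 0.111}
    supplements: {male: 0.081, female: 0.084}
    medications: {male: 0.031, female: 0.023}
    hyperlipidemia: {male: 0.043, female: 0.051}
    hypertension: {male: 0.035, female: 0.020}
    diabetes: {male: 0.048, female: 0.064}
    prior_mi: {male: 0.008, female: 0.008}
    heart_failure: {male: 0.012, female: 0.005}
    atrial_fibrillation: {male: 0.081, female: 0.106}
    prior_stroke_tia: {male: 0.006, female: 0.011}
    pad: {male: 0.519, female: 0.537}
    egfr: {male: 0.085, female: 0.115}
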