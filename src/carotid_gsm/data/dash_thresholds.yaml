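# DASH adherence-score component thresholds (editable).
#
# Each component scores 1 when `target` is met, 0.5 when `intermediate`
# is met, else 0.  `direction: ge` means higher intake is better,
# `direction: le` means lower is better.  Food-group values are
# servings/day; nutrients with `percent_energy: true` are converted from
# g/day to percent of energy using `kcal_per_gram`.
#
# Defaults are provisional values following the DASH guideline targets
# used by Folsom-style adherence scores (intermediate = halfway to the
# target for foods, a relaxed bound for nutrients); replace this file to
# use instrument-specific cutoffs.
components:
  grains:
    field: grains_servings
    direction: ge
    target: 6.0
    intermediate: 3.0
  vegetables:
    field: vegetables_servings
    direction: ge
    target: 4.0
    intermediate: 2.0
  fruits:
    field: fruits_servings
    direction: ge
    target: 4.0
    intermediate: 2.0
  dairy:
    field: dairy_servings
    direction: ge
    target: 2.0
    intermediate: 1.0
  meat_poultry_fish:
    field: meat_servings
    direction: le
    target: 2.0
    intermediate: 3.0
  nuts_seeds_legumes:
    field: nuts_legumes_servings
    direction: ge
    target: 0.57   # 4 servings/week
    intermediate: 0.29
  sweets:
    field: sweets_servings
    direction: le
    target: 0.71   # 5 servings/week
    intermediate: 1.14
  saturated_fat:
    field: saturated_fat_g
    direction: le
    percent_energy: true
    kcal_per_gram: 9.0
    target: 6.0
    intermediate: 11.0
  total_fat:
    field: total_fat_g
    direction: le
    percent_energy: true
    kcal_per_gram: 9.0
    target: 27.0
    intermediate: 32.0
  sodium:
    field: sodium_mg
    direction: le
    target: 2400.0
    intermediate: 3000.0
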