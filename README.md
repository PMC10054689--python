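# carotid_gsm

Measurement and modelling of carotid plaque echogenicity in a
population cohort, as one tested pipeline:

1. **Echogenicity** — turn an annotated B-mode ultrasound frame into
   normalized plaque gray-scale statistics. Brightness is anchored by
   two reference regions — the vessel lumen maps to gray value **0**
   and the adventitia to **190** via the linear map
   `g' = clip(round(190·(g−L)/(A−L)), 0, 255)` — and the plaque outline
   is rasterized with the even-odd rule at pixel centers. The
   participant-level outcome is the mean gray-scale value over all
   plaque × observer measurements (GSM); low GSM marks echolucent,
   lipid-rich, vulnerable plaque.
2. **Diet scores** — MEDAS (14 binary items, categories 0–3/4/5/6+) and
   a Folsom-style DASH adherence score (10 components scored 0/0.5/1,
   categories 0–3.5/3.6–4.5/4.6–5.0/5.1+) from FFQ-style intake tables,
   plus supplement-use coding with three-valued missing logic.
3. **Cohort models** — sex-stratified adjusted linear regressions for
   GSM, adjusted logistic regressions for plaque presence
   (OR = e^β), chained-equation multiple imputation (PMM / logistic /
   multinomial; m = 20 copies, 10 iterations) and Rubin's-rules pooling
   `T = W̄ + (1 + 1/m)·B` with Barnard–Rubin degrees of freedom.
4. **Synthetic data** — ultrasound-like frames with exactly known
   post-normalization plaque means, and cohorts with known effect
   sizes, prevalences and MAR missingness, so every estimate above can
   be checked by parameter recovery. The generator's defaults encode a
   10,000-participant cohort aged 45–74 with 21.6% plaque prevalence, a
   +9.12 GSM folate effect in men and a 1.18 high-vs-medium DASH odds
   ratio for plaque presence.

It is aimed at epidemiologists and imaging researchers who want a
reproducible, scriptable GSM + diet-score + MI-regression workflow
instead of a chain of GUI tools and ad-hoc scripts. See
`docs/methods.md` for the full model documentation.

## Worked example

```python
import numpy as np
from carotid_gsm import synthetic_data as sd, echogenicity as echo, cohort_models as cm

# a frame with a known plaque: measure it back
frame, ann, truth = sd.generate_image(sd.ImageSpec(seed=11))
res = echo.measure_frame(frame, ann)
print(f"plaque GSM: mean={res.gsm_mean:.2f} median={res.gsm_median:.1f} "
      f"(truth {truth.plaque_mean_norm:.2f}, n={res.n_pixels} px)")

# a cohort with a known DASH effect: estimate it back
table, t = sd.generate_cohort(n=20000, seed=11)
fit = cm.fit_plaque_logistic(table, exposure="dash")
row = fit.term("[T.high]")
print(f"DASH high vs medium: OR={row['or_']:.2f} "
      f"(95% CI {row['or_ci_low']:.2f}-{row['or_ci_high']:.2f}), true OR 1.18")
```

prints

```
plaque GSM: mean=56.97 median=57.0 (truth 56.50, n=2032 px)
DASH high vs medium: OR=1.17 (95% CI 1.07-1.28), true OR 1.18
```

The measured plaque mean sits within the Monte-Carlo noise of the
generator's ground truth (σ = 8 speckle over ~2,000 pixels), and the
adjusted logistic model recovers the odds ratio the cohort was
simulated with.

A CLI mirrors the library: `gsm simulate images|cohort`,
`gsm measure`, `gsm agree`, `gsm score`, `gsm fit` (see `--help`).

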