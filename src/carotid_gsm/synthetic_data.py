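"""Ground-truth synthetic data: ultrasound-like frames and cohorts.

Two generators make the whole pipeline testable by parameter recovery:

* :func:`generate_image` builds a frame with a dark lumen band, a bright
  adventitia band and an outlined plaque whose post-normalization mean
  gray value is known exactly, plus the matching annotation polygons.

* :func:`generate_cohort` draws an epidemiological cohort whose plaque
  prevalence, diet-score and supplement distributions, effect sizes and
  GSM outcome distribution are fixed by an editable specification
  (``data/cohort_defaults.yaml``); every dataset ships with the full
  truth record needed to score recovery.  :func:`inject_missingness`
  masks cells MCAR or MAR-on-sex at per-variable rates.

All operations are deterministic under a seed.
"""

from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from scipy.special import expit

from .echogenicity import AnnotationSet, UltrasoundFrame, rasterize_polygon
from .errors import SpecError

MEDAS_CATEGORIES = ("0-3", "4", "5", "6+")
DASH_CATEGORIES = ("0-3.5", "3.6-4.5", "4.6-5.0", "5.1+")
SUPPLEMENT_COLUMNS = (
    "multivitamins", "multiminerals", "calcium", "magnesium", "vitamin_B", "folate",
)

_CALIBRATION_SEED = 20160208  # fixed internal seed for intercept calibration
_CALIBRATION_N = 200_000
_intercept_cache: dict = {}


def default_cohort_spec() -> dict:
    """Deep copy of the shipped default cohort specification."""
    text = resources.files("carotid_gsm.data").joinpath("cohort_defaults.yaml").read_text()
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# images


@dataclass
class ImageSpec:
    """Geometry and intensity model of one synthetic frame.

    Gray means are on the raw 8-bit scale; ``plaque_mean_norm`` is the
    target plaque mean on the normalized (lumen=0, adventitia=190)
    scale.  Noise is additive Gaussian followed by rounding and clipping
    to the 8-bit range.
    """

    height: int = 128
    width: int = 128
    lumen_band: tuple = (10, 40)        # row range [start, stop)
    adventitia_band: tuple = (95, 120)
    lumen_mean: int = 25
    adventitia_mean: int = 215
    tissue_mean: int = 90
    plaque_center: tuple = (67.0, 64.0)  # (row, col)
    plaque_radii: tuple = (18.0, 36.0)   # (row, col) semi-axes
    plaque_mean_norm: float = 56.5
    noise_sigma: float = 8.0
    n_polygon_vertices: int = 40
    frame_id: str = "synthetic"
    observer_id: str = "generator"
    seed: object = None


@dataclass
class ImageGroundTruth:
    """Exact noiseless reference values for one generated frame."""

    plaque_mean_norm: float       # achieved (post-quantization) mean
    plaque_mean_norm_target: float
    lumen_median_raw: float
    adventitia_median_raw: float
    n_plaque_pixels: int
    plaque_mask: np.ndarray = field(repr=False, default=None)


def _ellipse_polygon(center, radii, n_vertices):
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    rows = center[0] + radii[0] * np.sin(theta)
    cols = center[1] + radii[1] * np.cos(theta)
    return np.column_stack([cols, rows])  # (x, y)


def _round_half_up(a):
    return np.floor(np.asarray(a, dtype=float) + 0.5)


def generate_image(spec: ImageSpec | None = None):
    """Generate ``(frame, annotation, ground_truth)`` for one plaque.

    The plaque region is defined by rasterizing the emitted polygon, so
    the annotation and the filled pixels agree exactly.  Fractional
    target means are realized by deterministic dithering between the two
    neighbouring gray levels; the ground truth records the achieved
    post-normalization mean, which the pipeline reproduces exactly at
    ``noise_sigma = 0``.
    """
    spec = spec or ImageSpec()
    if spec.noise_sigma < 0:
        raise SpecError("noise_sigma must be >= 0")
    if not spec.lumen_mean < spec.adventitia_mean:
        raise SpecError("adventitia must be brighter than lumen")

    scale = (spec.adventitia_mean - spec.lumen_mean) / 190.0
    raw_target = spec.lumen_mean + spec.plaque_mean_norm * scale
    if not spec.lumen_mean < raw_target < spec.adventitia_mean:
        raise SpecError("plaque mean must lie between lumen and adventitia levels")

    row_lo = spec.plaque_center[0] - spec.plaque_radii[0]
    row_hi = spec.plaque_center[0] + spec.plaque_radii[0]
    if row_lo < spec.lumen_band[1] or row_hi > spec.adventitia_band[0]:
        raise SpecError("plaque overlaps a reference band")

    dims = (spec.height, spec.width)
    polygon = _ellipse_polygon(spec.plaque_center, spec.plaque_radii,
                               spec.n_polygon_vertices)
    mask = rasterize_polygon(polygon, dims)
    n_plaque = int(mask.sum())

    img = np.full(dims, float(spec.tissue_mean))
    img[spec.lumen_band[0]:spec.lumen_band[1], :] = spec.lumen_mean
    img[spec.adventitia_band[0]:spec.adventitia_band[1], :] = spec.adventitia_mean

    base = int(np.floor(raw_target))
    frac = raw_target - base
    n_high = int(round(frac * n_plaque))
    plaque_vals = np.full(n_plaque, float(base))
    plaque_vals[:n_high] = base + 1  # deterministic dither in scan order
    img[mask] = plaque_vals

    # exact normalized plaque mean implied by the noiseless pixels
    norm_vals = np.clip(
        _round_half_up(190.0 * (img[mask] - spec.lumen_mean)
                       / (spec.adventitia_mean - spec.lumen_mean)),
        0, 255,
    )
    achieved = float(norm_vals.mean())

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=dims)
    pixels = np.clip(_round_half_up(img), 0, 255).astype(np.uint8)

    margin_x, margin_y = 8, 3
    lumen_poly = _rect_polygon(spec.lumen_band, spec.width, margin_x, margin_y)
    adv_poly = _rect_polygon(spec.adventitia_band, spec.width, margin_x, margin_y)

    frame = UltrasoundFrame(pixels=pixels, frame_id=spec.frame_id)
    annotation = AnnotationSet(
        frame_id=spec.frame_id,
        observer_id=spec.observer_id,
        plaque_polygon=polygon.tolist(),
        lumen_region=lumen_poly,
        adventitia_region=adv_poly,
    )
    truth = ImageGroundTruth(
        plaque_mean_norm=achieved,
        plaque_mean_norm_target=spec.plaque_mean_norm,
        lumen_median_raw=float(spec.lumen_mean),
        adventitia_median_raw=float(spec.adventitia_mean),
        n_plaque_pixels=n_plaque,
        plaque_mask=mask,
    )
    return frame, annotation, truth


def _rect_polygon(row_band, width, margin_x, margin_y):
    # odd pixel counts per side so the region median is a pixel value
    y0, y1 = row_band[0] + margin_y, row_band[1] - margin_y
    x0, x1 = margin_x, width - margin_x
    if (y1 - y0) % 2 == 0:
        y1 -= 1
    if (x1 - x0) % 2 == 0:
        x1 -= 1
    return [[x0, y0], [x1, y0], [x1, y1], [x0, y1]]


# ---------------------------------------------------------------------------
# distribution fitting helpers


def fit_shifted_gamma(median, q1, q3):
    """Shifted gamma (shape, loc, scale) matching three quartiles.

    Solves for the shape whose standardized quartile asymmetry
    (median - q1) / (q3 - q1) matches the data, then sets scale and
    location from the IQR and median.  Ratios below 0.5 correspond to
    right skew.
    """
    target = (median - q1) / (q3 - q1)
    if not 0 < target < 0.5:
        raise SpecError("quartiles do not describe a right-skewed distribution")

    def asymmetry(shape):
        g25, g50, g75 = stats.gamma.ppf([0.25, 0.5, 0.75], shape)
        return (g50 - g25) / (g75 - g25) - target

    shape = optimize.brentq(asymmetry, 0.02, 5000.0, xtol=1e-10)
    g25, g50, g75 = stats.gamma.ppf([0.25, 0.5, 0.75], shape)
    scale = (q3 - q1) / (g75 - g25)
    loc = median - scale * g50
    return float(shape), float(loc), float(scale)


def _lognormal_params(d):
    z75 = stats.norm.ppf(0.75)
    mu = np.log(d["median"])
    sigma = np.log(d["q3"] / d["q1"]) / (2 * z75)
    return mu, sigma


def _normal_params(d):
    z75 = stats.norm.ppf(0.75)
    return d["median"], (d["q3"] - d["q1"]) / (2 * z75)


def _draw_quantile_matched(d, n, rng):
    if d.get("family", "normal") == "lognormal":
        mu, sigma = _lognormal_params(d)
        return rng.lognormal(mu, sigma, size=n)
    mean, sd = _normal_params(d)
    return np.maximum(rng.normal(mean, sd, size=n), 0.0)


# ---------------------------------------------------------------------------
# cohort generation


def _validate_probs(spec):
    flat = [spec["female_frac"], *spec["education_probs"].values(),
            *spec["binary_prevalence"].values(),
            *spec["medas_probs"]["male"], *spec["medas_probs"]["female"],
            *spec["dash_probs"]["male"], *spec["dash_probs"]["female"],
            spec["supplements"]["any"]["male"], spec["supplements"]["any"]["female"]]
    for sexdict in spec["supplements"]["flags"].values():
        flat.extend(sexdict.values())
    if any(not 0 <= p <= 1 for p in flat):
        raise SpecError("all probabilities must lie in [0, 1]")


def _draw_covariates(n, spec, rng, tilt=None) -> pd.DataFrame:
    """Draw covariates; ``tilt`` optionally overrides the pre-selection
    diet-category and any-supplement probabilities (see
    :func:`calibrate_generator`)."""
    medas_probs = (tilt or {}).get("medas_probs", spec["medas_probs"])
    dash_probs = (tilt or {}).get("dash_probs", spec["dash_probs"])
    any_probs = (tilt or {}).get("any_supplement", spec["supplements"]["any"])
    female = rng.random(n) < spec["female_frac"]
    sex = np.where(female, "female", "male")
    df = pd.DataFrame({"sex": sex})
    df["age"] = rng.uniform(spec["age"]["min"], spec["age"]["max"], size=n)
    edu = spec["education_probs"]
    df["education"] = rng.choice(
        list(edu.keys()), size=n, p=np.asarray(list(edu.values())) / sum(edu.values())
    )
    b = spec["bmi"]
    df["bmi"] = np.clip(rng.normal(b["mean"], b["sd"], size=n), b["min"], b["max"])
    for name, prev in spec["binary_prevalence"].items():
        df[name] = rng.random(n) < prev

    for col in ("energy_kcal", "ses", "egfr"):
        vals = np.empty(n)
        for s in ("male", "female"):
            idx = df["sex"] == s
            vals[idx.to_numpy()] = _draw_quantile_matched(
                spec[col][s], int(idx.sum()), rng
            )
        df[col] = vals

    for col, cats, probs in (
        ("medas_category", MEDAS_CATEGORIES, medas_probs),
        ("dash_category", DASH_CATEGORIES, dash_probs),
    ):
        out = np.empty(n, dtype=object)
        for s in ("male", "female"):
            idx = (df["sex"] == s).to_numpy()
            p = np.asarray(probs[s], dtype=float)
            out[idx] = rng.choice(cats, size=int(idx.sum()), p=p / p.sum())
        df[col] = out

    # supplements: draw the any-flag, then tracked flags conditional on it
    # (the questionnaire also covers preparations beyond the six tracked
    # ones, so any-use can be true with every tracked flag false)
    any_supp = np.zeros(n, dtype=bool)
    for s in ("male", "female"):
        idx = (df["sex"] == s).to_numpy()
        any_supp[idx] = rng.random(int(idx.sum())) < any_probs[s]
    df["any_supplement"] = any_supp
    for flag, by_sex in spec["supplements"]["flags"].items():
        out = np.zeros(n, dtype=bool)
        for s in ("male", "female"):
            idx = ((df["sex"] == s) & any_supp).to_numpy()
            p_cond = by_sex[s] / spec["supplements"]["any"][s]
            if p_cond > 1:
                raise SpecError(f"flag {flag!r} prevalence exceeds any-supplement use")
            out[idx] = rng.random(int(idx.sum())) < p_cond
        df[flag] = out
    return df


def _plaque_linear_predictor(df, spec):
    pm = spec["plaque_model"]
    lo = {k: np.log(v) for k, v in pm["odds_ratios"].items()}
    centers = pm["centers"]
    s = np.zeros(len(df))
    s += lo["male_sex"] * (df["sex"] == "male").to_numpy()
    s += lo["age_per_year"] * (df["age"].to_numpy() - centers["age"])
    s += lo["education_low"] * (df["education"] == "low").to_numpy()
    s += lo["education_high"] * (df["education"] == "high").to_numpy()
    s += lo["bmi_per_unit"] * (df["bmi"].to_numpy() - centers["bmi"])
    for flag in ("diabetes", "hypertension", "hyperlipidemia", "smoking",
                 "heart_failure", "atrial_fibrillation", "prior_mi",
                 "prior_stroke_tia", "no_sports"):
        s += lo[flag] * df[flag].to_numpy()
    s += lo["medas_high"] * (df["medas_category"] == "6+").to_numpy()
    s += lo["medas_low"] * (df["medas_category"] == "0-3").to_numpy()
    s += lo["dash_high"] * (df["dash_category"] == "5.1+").to_numpy()
    s += lo["dash_low"] * (df["dash_category"] == "0-3.5").to_numpy()
    s += lo["any_supplement"] * df["any_supplement"].to_numpy()
    return s


def calibrate_generator(spec) -> dict:
    """Selection-consistent calibration of the generator.

    The specification's diet-category and supplement probabilities
    describe the *plaque-positive* sub-cohort (that is what the source
    descriptives tabulate), but diet categories and supplement use also
    enter the plaque model, so conditioning on plaque presence tilts
    their distribution.  This solves, on a fixed-seed calibration draw
    of 200,000 covariate vectors, for (a) the intercept giving the
    target marginal prevalence and (b) pre-selection ("tilted")
    per-sex probabilities for the MEDAS / DASH categories and the
    any-supplement flag such that their distributions conditional on
    plaque presence equal the specified values.  Tracked supplement
    flags are drawn conditionally on any-use at their target ratios and
    are independent of plaque presence given any-use, so they need no
    tilt of their own.  The fixed point is found by iterative
    importance reweighting and cached per specification.
    """
    key = json.dumps(
        {k: spec[k] for k in ("plaque_model", "female_frac", "age",
                              "education_probs", "bmi", "binary_prevalence",
                              "medas_probs", "dash_probs", "supplements")},
        sort_keys=True,
    )
    if key in _intercept_cache:
        return _intercept_cache[key]

    rng = np.random.default_rng(_CALIBRATION_SEED)
    cov = _draw_covariates(_CALIBRATION_N, spec, rng)
    s = _plaque_linear_predictor(cov, spec)
    target_prev = spec["plaque_model"]["target_prevalence"]

    sexes = ("male", "female")
    female = (cov["sex"] == "female").to_numpy()
    medas_codes = {c: (cov["medas_category"] == c).to_numpy() for c in MEDAS_CATEGORIES}
    dash_codes = {c: (cov["dash_category"] == c).to_numpy() for c in DASH_CATEGORIES}
    any_supp = cov["any_supplement"].to_numpy()

    tilt = {
        "medas_probs": {x: np.asarray(spec["medas_probs"][x], float).copy() for x in sexes},
        "dash_probs": {x: np.asarray(spec["dash_probs"][x], float).copy() for x in sexes},
        "any_supplement": {x: float(spec["supplements"]["any"][x]) for x in sexes},
    }
    base = {
        "medas_probs": {x: np.asarray(spec["medas_probs"][x], float) for x in sexes},
        "dash_probs": {x: np.asarray(spec["dash_probs"][x], float) for x in sexes},
        "any_supplement": {x: float(spec["supplements"]["any"][x]) for x in sexes},
    }

    b0 = 0.0
    for _ in range(60):
        # importance weights of the fixed calibration rows under the tilt
        w = np.ones(_CALIBRATION_N)
        for x, sel in (("male", ~female), ("female", female)):
            for j, c in enumerate(MEDAS_CATEGORIES):
                ratio = tilt["medas_probs"][x][j] / base["medas_probs"][x][j]
                w[sel & medas_codes[c]] *= ratio
            for j, c in enumerate(DASH_CATEGORIES):
                ratio = tilt["dash_probs"][x][j] / base["dash_probs"][x][j]
                w[sel & dash_codes[c]] *= ratio
            pa_t, pa_b = tilt["any_supplement"][x], base["any_supplement"][x]
            w[sel & any_supp] *= pa_t / pa_b
            w[sel & ~any_supp] *= (1 - pa_t) / (1 - pa_b)

        def excess(b):
            return float(np.average(expit(b + s), weights=w) - target_prev)

        b0 = optimize.brentq(excess, -25.0, 15.0, xtol=1e-9)
        pi = expit(b0 + s)
        wp = w * pi

        max_gap = 0.0
        for x, sel in (("male", ~female), ("female", female)):
            denom = wp[sel].sum()
            for kind, codes, cats in (("medas_probs", medas_codes, MEDAS_CATEGORIES),
                                      ("dash_probs", dash_codes, DASH_CATEGORIES)):
                share = np.array([wp[sel & codes[c]].sum() / denom for c in cats])
                targ = base[kind][x]
                max_gap = max(max_gap, float(np.max(np.abs(share - targ))))
                upd = tilt[kind][x] * targ / np.maximum(share, 1e-12)
                tilt[kind][x] = upd / upd.sum()
            share_a = wp[sel & any_supp].sum() / denom
            targ_a = base["any_supplement"][x]
            max_gap = max(max_gap, abs(share_a - targ_a))
            pa = tilt["any_supplement"][x]
            num = pa * targ_a / max(share_a, 1e-12)
            den = num + (1 - pa) * (1 - targ_a) / max(1 - share_a, 1e-12)
            tilt["any_supplement"][x] = num / den
        if max_gap < 1e-7:
            break

    result = {
        "intercept": float(b0),
        "medas_probs": {x: tilt["medas_probs"][x].tolist() for x in sexes},
        "dash_probs": {x: tilt["dash_probs"][x].tolist() for x in sexes},
        "any_supplement": {x: float(v) for x, v in tilt["any_supplement"].items()},
    }
    _intercept_cache[key] = result
    return result


def calibrate_plaque_intercept(spec) -> float:
    """Calibrated plaque-model intercept (see :func:`calibrate_generator`)."""
    return calibrate_generator(spec)["intercept"]


def gsm_distribution_params(spec=None) -> dict:
    """Fitted shifted-gamma GSM parameters per sex."""
    spec = spec or default_cohort_spec()
    return {
        s: fit_shifted_gamma(spec["gsm_model"][s]["median"],
                             spec["gsm_model"][s]["q1"],
                             spec["gsm_model"][s]["q3"])
        for s in ("male", "female")
    }


def sample_gsm(sex: str, n: int, seed=None, spec=None) -> np.ndarray:
    """Draw ``n`` baseline GSM values from the per-sex residual model."""
    shape, loc, scale = gsm_distribution_params(spec)[sex]
    rng = np.random.default_rng(seed)
    return np.clip(loc + rng.gamma(shape, scale, size=n), 0.0, 255.0)


def generate_cohort(spec: dict | None = None, n: int | None = None, seed=None):
    """Simulate a cohort table plus its ground-truth parameter record.

    Returns ``(table, truth)`` where ``truth`` stores the calibrated
    plaque-model intercept, every log-odds coefficient, the fitted GSM
    distribution parameters and the GSM effect coefficients.
    """
    spec = _copy.deepcopy(spec) if spec is not None else default_cohort_spec()
    _validate_probs(spec)
    n = int(n if n is not None else spec["n"])
    if n < 1:
        raise SpecError("n must be >= 1")

    calibration = calibrate_generator(spec)
    rng = np.random.default_rng(seed)
    df = _draw_covariates(n, spec, rng, tilt=calibration)
    df.insert(0, "participant_id", [f"P{i:07d}" for i in range(n)])

    b0 = calibration["intercept"]
    lin = b0 + _plaque_linear_predictor(df, spec)
    df["plaque_present"] = rng.random(n) < expit(lin)

    gamma_params = gsm_distribution_params(spec)
    gsm = np.full(n, np.nan)
    for s in ("male", "female"):
        idx = ((df["sex"] == s) & df["plaque_present"]).to_numpy()
        k = int(idx.sum())
        shape, loc, scale = gamma_params[s]
        vals = loc + rng.gamma(shape, scale, size=k)
        effects = spec["gsm_model"]["effects"].get(s) or {}
        sub = df.loc[idx]
        for col, beta in effects.items():
            vals = vals + beta * sub[col].to_numpy()
        gsm[idx] = np.clip(vals, 0.0, 255.0)
    df["gsm"] = gsm

    truth = {
        "plaque_intercept": b0,
        "calibration": calibration,
        "plaque_log_odds": {k: float(np.log(v))
                            for k, v in spec["plaque_model"]["odds_ratios"].items()},
        "gsm_gamma": {s: tuple(gamma_params[s]) for s in gamma_params},
        "gsm_effects": _copy.deepcopy(spec["gsm_model"]["effects"]),
        "target_prevalence": spec["plaque_model"]["target_prevalence"],
        "spec": spec,
    }
    return df, truth


# ---------------------------------------------------------------------------
# missingness


def inject_missingness(
    table: pd.DataFrame,
    rates: dict | None = None,
    mechanism: str | None = None,
    seed=None,
    blocks: dict | None = None,
):
    """Mask cells at per-variable rates; returns ``(masked, original)``.

    ``rates`` maps a variable or block name to either a single rate
    (MCAR) or ``{'male': r, 'female': r}`` (MAR-on-sex: the missingness
    probability depends on the observed sex).  Variables listed together
    in a block (e.g. one questionnaire section) are masked jointly with
    one draw per row.
    """
    spec_missing = default_cohort_spec()["missingness"]
    rates = rates if rates is not None else spec_missing["rates"]
    blocks = blocks if blocks is not None else spec_missing["blocks"]
    mechanism = mechanism or spec_missing["mechanism"]
    if mechanism not in ("mcar", "mar_sex"):
        raise SpecError(f"unknown missingness mechanism {mechanism!r}")

    rng = np.random.default_rng(seed)
    out = table.copy()
    n = len(out)
    for name, rate in rates.items():
        cols = blocks.get(name, [name])
        cols = [c for c in cols if c in out.columns]
        if not cols:
            continue
        if isinstance(rate, dict):
            if any(not 0 <= r <= 1 for r in rate.values()):
                raise SpecError(f"rate for {name!r} outside [0, 1]")
            if mechanism == "mcar":
                p = np.full(n, float(np.mean(list(rate.values()))))
            else:
                p = np.where(out["sex"] == "female",
                             rate.get("female", 0.0), rate.get("male", 0.0))
        else:
            if not 0 <= rate <= 1:
                raise SpecError(f"rate for {name!r} outside [0, 1]")
            p = np.full(n, float(rate))
        mask = rng.random(n) < p
        for c in cols:
            if out[c].dtype == bool:
                out[c] = out[c].astype(object)
            out.loc[mask, c] = np.nan
    return out, table
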