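"""FFQ aggregation and dietary-adherence scoring (MEDAS, DASH).

MEDAS (Mediterranean Diet Adherence Screener) is a 14-item screener;
each item scores 1 for adherence and 0 otherwise, so totals run 0-14 and
are grouped into the categories 0-3, 4, 5 and 6+.

The DASH adherence score follows the Folsom-style adaptation: 10
components (7 food groups: grains, vegetables, fruits, dairy,
meat/poultry/fish, nuts/seeds/legumes, sweets; 3 nutrients: saturated
fat, total fat, sodium), each scored 1 when the DASH target is met, 0.5
at an intermediate threshold and 0 otherwise.  Totals run 0-10 in steps
of 0.5 and are grouped into 0-3.5, 3.6-4.5, 4.6-5.0 and 5.1+.

Component thresholds are configuration, not code: the shipped defaults
(``data/dash_thresholds.yaml``) follow published DASH guideline targets
and can be replaced wholesale by the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

MEDAS_N_ITEMS = 14
MEDAS_CATEGORIES = ("0-3", "4", "5", "6+")
DASH_CATEGORIES = ("0-3.5", "3.6-4.5", "4.6-5.0", "5.1+")

#: Supplement flags tracked by the cohort analysis (used >=1 month in the
#: last 12 months).
SUPPLEMENT_FLAGS = (
    "multivitamins",
    "multiminerals",
    "calcium",
    "magnesium",
    "vitamin_B",
    "folate",
)

PROFILE_FIELDS = (
    "energy_kcal",
    "saturated_fat_g",
    "total_fat_g",
    "sodium_mg",
    "grains_servings",
    "vegetables_servings",
    "fruits_servings",
    "dairy_servings",
    "meat_servings",
    "nuts_legumes_servings",
    "sweets_servings",
)


@dataclass
class NutrientProfile:
    """Daily nutrient and food-group intake derived from an FFQ record."""

    participant_id: str
    values: dict

    def __getitem__(self, key):
        return self.values[key]


@dataclass
class MedasScore:
    participant_id: str
    items: list
    total: int
    category: str
    missing_items: list = field(default_factory=list)


@dataclass
class DashScore:
    participant_id: str
    items: dict
    total: float
    category: str
    missing_components: list = field(default_factory=list)


@dataclass
class SupplementProfile:
    participant_id: str
    flags: dict          # flag -> True / False / None (missing)
    any_supplement: object  # True / False / None


# ---------------------------------------------------------------------------


def ffq_to_profile(
    participant_id: str,
    intakes: pd.DataFrame,
    composition_table: pd.DataFrame,
) -> NutrientProfile:
    """Aggregate FFQ item intakes into a daily nutrient profile.

    Parameters
    ----------
    intakes : DataFrame indexed by item id with columns ``frequency``
        (times/day) and ``portion_g`` (grams per occasion).
    composition_table : DataFrame indexed by item id with one per-gram
        coefficient column per profile field (missing columns are
        treated as zero contribution).

    Every output field is Sigma_item frequency * portion * coefficient,
    i.e. linear in the intakes.
    """
    unknown = intakes.index.difference(composition_table.index)
    if len(unknown):
        raise KeyError(
            "FFQ items missing from composition table: " + ", ".join(map(str, unknown))
        )
    if (intakes[["frequency", "portion_g"]] < 0).any().any():
        raise ValueError("frequencies and portions must be non-negative")
    grams_per_day = intakes["frequency"] * intakes["portion_g"]
    comp = composition_table.loc[intakes.index]
    values = {}
    for fld in PROFILE_FIELDS:
        coef = comp[fld] if fld in comp.columns else 0.0
        values[fld] = float((grams_per_day * coef).sum())
    return NutrientProfile(participant_id=participant_id, values=values)


def medas_category(total: int) -> str:
    if total <= 3:
        return "0-3"
    if total == 4:
        return "4"
    if total == 5:
        return "5"
    return "6+"


def score_medas(participant_id: str, responses) -> MedasScore:
    """Score the 14 MEDAS adherence indicators.

    ``responses`` is a sequence of 14 values in {0, 1, None/NaN}; a
    missing item contributes 0 and is recorded in ``missing_items``.
    """
    responses = list(responses)
    if len(responses) != MEDAS_N_ITEMS:
        raise ValueError(f"MEDAS needs exactly {MEDAS_N_ITEMS} items, got {len(responses)}")
    items, missing = [], []
    for i, r in enumerate(responses):
        if r is None or (isinstance(r, float) and np.isnan(r)):
            items.append(0)
            missing.append(i)
        elif r in (0, 1):
            items.append(int(r))
        else:
            raise ValueError(f"MEDAS item {i} must be 0, 1 or missing; got {r!r}")
    total = int(sum(items))
    return MedasScore(
        participant_id=participant_id,
        items=items,
        total=total,
        category=medas_category(total),
        missing_items=missing,
    )


def dash_category(total: float) -> str:
    # 0.5-step totals make the (4.5, 4.6) and (5.0, 5.1) gaps unreachable
    if total <= 3.5:
        return "0-3.5"
    if total <= 4.5:
        return "3.6-4.5"
    if total <= 5.0:
        return "4.6-5.0"
    return "5.1+"


def load_dash_thresholds() -> dict:
    """Shipped default DASH component thresholds (editable YAML)."""
    text = resources.files("carotid_gsm.data").joinpath("dash_thresholds.yaml").read_text()
    return yaml.safe_load(text)


def _component_value(profile: NutrientProfile, spec: dict):
    value = profile.values.get(spec["field"])
    if value is None:
        return None
    if spec.get("percent_energy"):
        energy = profile.values.get("energy_kcal") or np.nan
        if not energy or np.isnan(energy) or energy <= 0:
            return None
        value = 100.0 * value * spec["kcal_per_gram"] / energy
    return value


def score_dash(
    participant_id: str,
    profile: NutrientProfile,
    thresholds: dict | None = None,
) -> DashScore:
    """Score the 10 DASH components from a nutrient profile.

    Each component scores 1 when the target is met, 0.5 at the
    intermediate threshold, else 0.  Components whose inputs are missing
    score 0 (conservative) and are flagged in ``missing_components``.
    """
    thresholds = thresholds or load_dash_thresholds()
    items, missing = {}, []
    for name, spec in thresholds["components"].items():
        value = _component_value(profile, spec)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            items[name] = 0.0
            missing.append(name)
            continue
        if spec["direction"] == "ge":
            met, inter = value >= spec["target"], value >= spec["intermediate"]
        else:
            met, inter = value <= spec["target"], value <= spec["intermediate"]
        items[name] = 1.0 if met else (0.5 if inter else 0.0)
    total = float(sum(items.values()))
    return DashScore(
        participant_id=participant_id,
        items=items,
        total=total,
        category=dash_category(total),
        missing_components=missing,
    )


def code_supplements(
    participant_id: str, questionnaire_flags: dict, tracked=SUPPLEMENT_FLAGS
) -> SupplementProfile:
    """Copy tracked supplement flags and derive ``any_supplement``.

    Flags are True / False / None (missing).  The any-flag is a
    three-valued OR: True if any tracked flag is True, False if all are
    False, otherwise missing (None) — missingness propagates so that the
    imputation stage can handle it.
    """
    flags = {}
    for name in tracked:
        v = questionnaire_flags.get(name)
        if v is not None and not isinstance(v, (bool, np.bool_)):
            if isinstance(v, float) and np.isnan(v):
                v = None
            else:
                raise ValueError(f"supplement flag {name!r} must be boolean or missing")
        flags[name] = None if v is None else bool(v)
    vals = list(flags.values())
    if any(v is True for v in vals):
        any_supp = True
    elif all(v is False for v in vals):
        any_supp = False
    else:
        any_supp = None
    return SupplementProfile(
        participant_id=participant_id, flags=flags, any_supplement=any_supp
    )


def score_table(
    ffq: pd.DataFrame,
    composition_table: pd.DataFrame,
    medas_responses: pd.DataFrame | None = None,
    thresholds: dict | None = None,
) -> pd.DataFrame:
    """Score a whole cohort: one row per participant.

    ``ffq`` is long-format with columns participant_id, item, frequency,
    portion_g.  ``medas_responses`` (optional) is wide with columns
    item_1..item_14 indexed by participant_id.
    """
    rows = []
    for pid, grp in ffq.groupby("participant_id"):
        intakes = grp.set_index("item")[["frequency", "portion_g"]]
        profile = ffq_to_profile(str(pid), intakes, composition_table)
        dash = score_dash(str(pid), profile, thresholds)
        row = {
            "participant_id": pid,
            "energy_kcal": profile["energy_kcal"],
            "dash_total": dash.total,
            "dash_category": dash.category,
        }
        if medas_responses is not None and pid in medas_responses.index:
            medas = score_medas(str(pid), medas_responses.loc[pid].tolist())
            row["medas_total"] = medas.total
            row["medas_category"] = medas.category
        rows.append(row)
    return pd.DataFrame(rows)
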