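"""Sex-stratified cohort models with multiple imputation and pooling.

The inferential stage of the pipeline: adjusted linear regressions for
plaque echogenicity (GSM) within the plaque sub-cohort, adjusted
logistic regressions for plaque presence in the full cohort, Rubin's
rules for combining per-imputation fits, and Table-1 style descriptive
summaries (median [IQR] / n (%) with rank-sum / chi-squared
between-sex comparisons).  No multiple-comparison adjustment is applied
anywhere; significance is a two-sided alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._mice import ImputationSet, infer_variable_types, mice_impute  # noqa: F401
from .errors import CarotidGsmError, InsufficientDataError, SeparationError

ALPHA = 0.05

#: Adjustment set of the linear GSM models (plaque sub-cohort, per sex).
GSM_MODEL_COVARIATES = [
    "age", "ses", "no_sports", "bmi", "smoking", "energy_kcal",
    "hyperlipidemia", "hypertension", "diabetes", "prior_mi",
    "heart_failure", "atrial_fibrillation", "prior_stroke_tia", "pad",
    "egfr", "lipid_lowering", "antihypertensives", "antidiabetics",
    "antiplatelets",
]

#: Adjustment set of the logistic plaque-presence models (full cohort).
PLAQUE_MODEL_COVARIATES = [
    "age", "sex", "education", "bmi", "diabetes", "hypertension",
    "hyperlipidemia", "smoking", "heart_failure", "atrial_fibrillation",
    "prior_mi", "prior_stroke_tia", "no_sports",
]

#: Diet-exposure codings of the linear models: category dummies against
#: the lowest category.
EXPOSURE_FORMULAS = {
    "medas": "C(medas_category, Treatment(reference='0-3'))",
    "dash": "C(dash_category, Treatment(reference='0-3.5'))",
}

MEDAS_GROUP = {"0-3": "low", "4": "medium", "5": "medium", "6+": "high"}
DASH_GROUP = {"0-3.5": "low", "3.6-4.5": "medium", "4.6-5.0": "medium", "5.1+": "high"}


def categorize_education(isced_level):
    """Map an ISCED 2011 level (0-8) to low / medium / high.

    Declared cut: 0-2 low, 3-4 medium, 5-8 high.  Missing propagates.
    """
    if isced_level is None or (isinstance(isced_level, float) and np.isnan(isced_level)):
        return None
    level = int(isced_level)
    if not 0 <= level <= 8:
        raise ValueError(f"ISCED level must be 0-8, got {isced_level}")
    if level <= 2:
        return "low"
    if level <= 4:
        return "medium"
    return "high"


def add_exposure_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse the four diet-score categories to low / medium / high.

    MEDAS: low = 0-3, medium = 4 & 5, high = 6+.
    DASH:  low = 0-3.5, medium = 3.6-4.5 & 4.6-5.0, high = 5.1+.
    """
    out = table.copy()
    if "medas_category" in out:
        out["medas_group"] = out["medas_category"].map(MEDAS_GROUP)
    if "dash_category" in out:
        out["dash_group"] = out["dash_category"].map(DASH_GROUP)
    return out


# ---------------------------------------------------------------------------
# Rubin's rules


@dataclass
class PooledFit:
    """Rubin-pooled regression fit.

    ``table`` has one row per model term: estimate, se, W (within), B
    (between), T (total variance), df (Barnard-Rubin), ci_low, ci_high,
    p.  For logistic fits ``or_``, ``or_ci_low``, ``or_ci_high`` hold
    the exponentiated scale.
    """

    table: pd.DataFrame
    family: str
    stratum: str
    m: int

    def term(self, pattern: str) -> pd.Series:
        hits = self.table.index[self.table.index.str.contains(pattern, regex=False)]
        if len(hits) != 1:
            raise KeyError(f"pattern {pattern!r} matches {len(hits)} terms")
        return self.table.loc[hits[0]]


def pool_rubin(
    estimates,
    variances,
    terms=None,
    n_obs: int | None = None,
    n_params: int | None = None,
    family: str = "linear",
    stratum: str = "all",
) -> PooledFit:
    """Combine per-imputation estimates by Rubin's rules.

    Q-bar = mean estimate, W-bar = mean within-imputation variance,
    B = sample variance of estimates, T = W-bar + (1 + 1/m) B.  Degrees
    of freedom follow Barnard-Rubin when the complete-data sample size
    is supplied, else the classic large-sample formula (m-1)/lambda^2.
    """
    Q = np.atleast_2d(np.asarray(estimates, dtype=float))
    U = np.atleast_2d(np.asarray(variances, dtype=float))
    if Q.shape != U.shape:
        raise CarotidGsmError("estimates and variances must align")
    m, p = Q.shape
    if m < 2:
        raise InsufficientDataError("Rubin pooling needs m >= 2 imputations")
    if terms is None:
        terms = [f"b{j}" for j in range(p)]
    if len(terms) != p:
        raise CarotidGsmError("terms do not match the fitted coefficients")

    qbar = Q.mean(axis=0)
    wbar = U.mean(axis=0)
    B = Q.var(axis=0, ddof=1)
    T = wbar + (1 + 1 / m) * B

    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(T > 0, (1 + 1 / m) * B / T, 0.0)
        df_old = np.where(lam > 0, (m - 1) / lam**2, np.inf)
    if n_obs is not None:
        nu_com = max((n_obs - (n_params if n_params is not None else p)), 1)
        df_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
        df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    else:
        df = df_old
    df = np.where(np.isfinite(df), df, 1e9)

    se = np.sqrt(T)
    tcrit = stats.t.ppf(1 - ALPHA / 2, df)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, qbar / se, np.inf * np.sign(qbar))
    pval = 2 * stats.t.sf(np.abs(tval), df)

    table = pd.DataFrame(
        {
            "estimate": qbar, "se": se, "W": wbar, "B": B, "T": T,
            "df": df, "ci_low": qbar - tcrit * se, "ci_high": qbar + tcrit * se,
            "p": pval,
        },
        index=pd.Index(terms, name="term"),
    )
    if family == "logistic":
        table["or_"] = np.exp(table["estimate"])
        table["or_ci_low"] = np.exp(table["ci_low"])
        table["or_ci_high"] = np.exp(table["ci_high"])
    return PooledFit(table=table, family=family, stratum=stratum, m=m)


# ---------------------------------------------------------------------------
# model fitting


def _as_imputations(data) -> list:
    if isinstance(data, ImputationSet):
        return list(data.copies)
    return [data]


def _prepare(df: pd.DataFrame, columns) -> pd.DataFrame:
    """Coerce booleans to floats; keep categories as strings."""
    out = df[columns].copy()
    for c in out.columns:
        if out[c].dtype == bool or out[c].dtype == object and set(
            out[c].dropna().unique()
        ) <= {True, False}:
            if c not in ("sex", "education", "medas_category", "dash_category",
                         "medas_group", "dash_group"):
                out[c] = out[c].astype(float)
    return out


def _check_rank(res, formula):
    exog = res.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        names = res.model.exog_names
        _, R = np.linalg.qr(exog)
        aliased = [names[j] for j in range(len(names)) if abs(R[j, j]) < 1e-8]
        raise CarotidGsmError(
            f"rank-deficient design for {formula!r}; aliased terms: {aliased}"
        )


def fit_gsm_linear(
    data,
    exposure: str,
    stratum: str = "men",
    covariates=None,
) -> PooledFit:
    """Adjusted linear regression of GSM on a dietary exposure.

    ``exposure`` is ``'medas'``, ``'dash'``, a supplement flag column,
    or any binary column.  Fit on the plaque sub-cohort rows (gsm
    present) of the requested sex stratum within each imputed copy and
    pooled with Rubin's rules.
    """
    covariates = GSM_MODEL_COVARIATES if covariates is None else list(covariates)
    exposure_term = EXPOSURE_FORMULAS.get(exposure, exposure)
    rhs = " + ".join([exposure_term] + covariates) if (covariates or exposure_term) else "1"
    formula = f"gsm ~ {rhs}"

    params, variances, names = [], [], None
    n_used = None
    for copy in _as_imputations(data):
        sub = copy[copy["gsm"].notna()] if "gsm" in copy else copy
        if stratum == "men":
            sub = sub[sub["sex"] == "male"]
        elif stratum == "women":
            sub = sub[sub["sex"] == "female"]
        if sub.empty:
            raise InsufficientDataError(f"stratum {stratum!r} is empty")
        cols = ["gsm", "sex"] + covariates
        if exposure == "medas":
            cols.append("medas_category")
        elif exposure == "dash":
            cols.append("dash_category")
        else:
            cols.append(exposure)
        sub = _prepare(sub, list(dict.fromkeys(cols))).dropna()
        if sub.empty:
            raise InsufficientDataError("no complete rows to fit on")
        res = smf.ols(formula, data=sub).fit()
        _check_rank(res, formula)
        names = list(res.params.index)
        params.append(res.params.to_numpy())
        variances.append(res.bse.to_numpy() ** 2)
        n_used = len(sub)
    return pool_rubin(
        params, variances, terms=names, n_obs=n_used, n_params=len(names),
        family="linear", stratum=stratum,
    )


def fit_plaque_logistic(
    data,
    exposure: str = "dash",
    covariates=None,
) -> PooledFit:
    """Adjusted logistic regression for presence of >=1 carotid plaque.

    ``exposure``: ``'medas'`` / ``'dash'`` (high & low vs medium
    adherence), ``'any_supplement'`` (yes vs no), or any binary column.
    Accepts either an ImputationSet (pooled by Rubin's rules) or a
    single table (complete-case fit).
    """
    covariates = PLAQUE_MODEL_COVARIATES if covariates is None else list(covariates)
    if exposure == "medas":
        exposure_term = "C(medas_group, Treatment(reference='medium'))"
        needed = ["medas_category"]
    elif exposure == "dash":
        exposure_term = "C(dash_group, Treatment(reference='medium'))"
        needed = ["dash_category"]
    else:
        exposure_term = exposure
        needed = [exposure]
    rhs = " + ".join([exposure_term] + covariates) if (covariates or exposure_term) else "1"
    formula = f"plaque_present ~ {rhs}"

    copies = _as_imputations(data)
    params, variances, names, n_used = [], [], None, None
    for copy in copies:
        sub = add_exposure_groups(copy)
        cols = ["plaque_present"] + needed + covariates
        if exposure in ("medas", "dash"):
            cols.append("medas_group" if exposure == "medas" else "dash_group")
        sub = _prepare(sub, list(dict.fromkeys(c for c in cols if c in sub.columns)))
        sub = sub.dropna()
        y = sub["plaque_present"].astype(float)
        if y.nunique() < 2:
            raise InsufficientDataError("plaque outcome has a single class")
        sub = sub.assign(plaque_present=y)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.logit(formula, data=sub).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as err:
            raise SeparationError(f"complete separation in logistic fit: {err}")
        if not res.mle_retvals.get("converged", True) or np.any(res.bse > 1e3):
            raise SeparationError("logistic fit did not converge (separation suspected)")
        _check_rank(res, formula)
        names = list(res.params.index)
        params.append(res.params.to_numpy())
        variances.append(res.bse.to_numpy() ** 2)
        n_used = len(sub)

    if len(copies) == 1:
        # complete-case: Wald inference from the single ML fit
        est, var = params[0], variances[0]
        se = np.sqrt(var)
        z = stats.norm.ppf(1 - ALPHA / 2)
        table = pd.DataFrame(
            {
                "estimate": est, "se": se, "W": var, "B": 0.0, "T": var,
                "df": np.inf, "ci_low": est - z * se, "ci_high": est + z * se,
                "p": 2 * stats.norm.sf(np.abs(est / se)),
            },
            index=pd.Index(names, name="term"),
        )
        table["or_"] = np.exp(table["estimate"])
        table["or_ci_low"] = np.exp(table["ci_low"])
        table["or_ci_high"] = np.exp(table["ci_high"])
        return PooledFit(table=table, family="logistic", stratum="all", m=1)
    return pool_rubin(
        params, variances, terms=names, n_obs=n_used, n_params=len(names),
        family="logistic", stratum="all",
    )


# ---------------------------------------------------------------------------
# descriptives


def descriptive_table(table: pd.DataFrame, group_by: str = "sex") -> pd.DataFrame:
    """Table-1 style summary with between-group comparison p-values.

    Continuous variables: median [IQR], Wilcoxon rank-sum test.
    Categorical/binary: n (%), chi-squared test.  NA counts reported
    per variable.  Percentages use the full group size as denominator
    (missing rows included), matching epidemiological reporting.
    """
    if table.empty:
        raise InsufficientDataError("empty table")
    groups = [g for g in table[group_by].dropna().unique()]
    types = infer_variable_types(table, ignore=("participant_id", group_by))

    def fmt_cont(s):
        s = s.dropna()
        if s.empty:
            return "-"
        return f"{s.median():.2f} ({s.quantile(.25):.2f}, {s.quantile(.75):.2f})"

    rows = []
    for col, kind in types.items():
        row = {"variable": col, "type": kind, "n_missing": int(table[col].isna().sum())}
        if kind == "numeric":
            row["overall"] = fmt_cont(table[col])
            samples = []
            for g in groups:
                s = table.loc[table[group_by] == g, col]
                row[str(g)] = fmt_cont(s)
                samples.append(s.dropna())
            if len(samples) == 2 and all(len(s) for s in samples):
                row["p"] = float(stats.mannwhitneyu(*samples).pvalue)
        else:
            if kind == "binary":
                vals = table[col].astype(float)
                n, denom = int(vals.sum()), len(vals)
                row["overall"] = f"{n} ({100 * n / denom:.1f})"
                cells = []
                for g in groups:
                    s = vals[table[group_by] == g]
                    k, d = int(s.sum()), len(s)
                    row[str(g)] = f"{k} ({100 * k / d:.1f})"
                    cells.append([k, int(s.notna().sum()) - k])
                tab = np.array(cells).T
            else:
                levels = sorted(table[col].dropna().unique())
                row["overall"] = "; ".join(
                    f"{lv}: {int((table[col] == lv).sum())}"
                    f" ({100 * (table[col] == lv).mean():.1f})"
                    for lv in levels
                )
                for g in groups:
                    s = table.loc[table[group_by] == g, col]
                    row[str(g)] = "; ".join(
                        f"{lv}: {int((s == lv).sum())} ({100 * (s == lv).mean():.1f})"
                        for lv in levels
                    )
                tab = np.array(
                    [[int(((table[group_by] == g) & (table[col] == lv)).sum())
                      for g in groups] for lv in levels]
                )
            tab = tab[:, tab.sum(axis=0) > 0]
            tab = tab[tab.sum(axis=1) > 0]
            if tab.shape[0] >= 2 and tab.shape[1] >= 2:
                row["p"] = float(stats.chi2_contingency(tab).pvalue)
        rows.append(row)
    return pd.DataFrame(rows)
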