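"""Chained-equations multiple imputation engine.

Implements MICE with the univariate model families used by the cohort
analysis: type-1 predictive mean matching (PMM) for numeric variables,
posterior-draw logistic regression for binary variables and multinomial
logistic regression for categorical variables.  Each of the ``m``
completed copies runs its own chain for ``iterations`` sweeps; within a
sweep, variables are visited in order of increasing missingness and each
is regressed on all other variables (one-hot encoded, standardized,
intercept added).

PMM and the logistic family draw regression parameters from their
large-sample posterior before imputing, which propagates estimation
uncertainty into the between-imputation variance.  The multinomial step
draws classes from the ML fit's predicted probabilities without a
parameter draw (a small understatement of between-imputation variance,
documented in the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import expit, softmax

from .errors import CarotidGsmError

_PMM_DONORS = 5
_RIDGE = 1e-6


@dataclass
class ImputationSet:
    """``m`` completed copies of a cohort table."""

    copies: list
    m: int
    iterations: int
    seed: object = None

    def __iter__(self):
        return iter(self.copies)

    def __len__(self):
        return self.m


def infer_variable_types(df: pd.DataFrame, ignore=()) -> dict:
    """Classify columns as numeric / binary / categorical."""
    types = {}
    for col in df.columns:
        if col in ignore:
            continue
        s = df[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            types[col] = "categorical"
        elif s.dtype == bool:
            types[col] = "binary"
        else:
            observed = s.dropna().unique()
            if len(observed) <= 2 and set(np.asarray(observed, dtype=float)) <= {0.0, 1.0}:
                types[col] = "binary"
            else:
                types[col] = "numeric"
    return types


class _Column:
    """Numeric working representation of one table column."""

    def __init__(self, series: pd.Series, kind: str):
        self.kind = kind
        self.name = series.name
        self.missing = series.isna().to_numpy()
        if kind == "categorical":
            cat = series.astype("category")
            self.categories = list(cat.cat.categories)
            codes = cat.cat.codes.to_numpy().astype(np.int64)  # -1 = missing
            self.values = codes
        else:
            self.values = series.astype(float).to_numpy(copy=True)

    def design_block(self) -> np.ndarray:
        """Column(s) this variable contributes as a *predictor*."""
        if self.kind == "categorical":
            k = len(self.categories)
            out = np.zeros((self.values.size, max(k - 1, 1)))
            for j in range(1, k):
                out[:, j - 1] = self.values == j
            return out
        return self.values[:, None]

    def to_series(self, index) -> pd.Series:
        if self.kind == "categorical":
            return pd.Series(
                pd.Categorical.from_codes(self.values, categories=self.categories),
                index=index,
                name=self.name,
            ).astype(object)
        return pd.Series(self.values, index=index, name=self.name)


def _draw_mvn_from_precision(beta_hat, chol_lower, rng, scale=1.0):
    """Draw from N(beta_hat, scale * (L L')^{-1}) given L = chol(precision)."""
    z = rng.standard_normal(beta_hat.size)
    return beta_hat + np.sqrt(scale) * linalg.solve_triangular(
        chol_lower.T, z, lower=False
    )


def _pmm_step(X_obs, y_obs, X_mis, rng):
    n_obs, p = X_obs.shape
    xtx = X_obs.T @ X_obs + _RIDGE * np.eye(p)
    beta_hat = linalg.solve(xtx, X_obs.T @ y_obs, assume_a="pos")
    resid = y_obs - X_obs @ beta_hat
    nu = max(n_obs - p, 1)
    rss = float(resid @ resid)
    sigma2_star = rss / rng.chisquare(nu) if rss > 0 else 0.0
    L = linalg.cholesky(xtx, lower=True)
    beta_star = _draw_mvn_from_precision(beta_hat, L, rng, scale=max(sigma2_star, 1e-12))

    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_star
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    # candidate window of 2k donors around the insertion point
    k = _PMM_DONORS
    offsets = np.arange(-k, k)
    cand = np.clip(pos[:, None] + offsets[None, :], 0, n_obs - 1)
    dist = np.abs(sorted_pred[cand] - pred_mis[:, None])
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]
    pick = nearest[np.arange(len(pred_mis)), rng.integers(0, k, size=len(pred_mis))]
    donor_rows = order[cand[np.arange(len(pred_mis)), pick]]
    return y_obs[donor_rows]


def _irls_logistic(X, y, beta0=None, max_iter=25, tol=1e-6):
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    A = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        w = mu * (1 - mu) + 1e-10
        A = X.T @ (X * w[:, None]) + _RIDGE * np.eye(p)
        grad = X.T @ (y - mu) - _RIDGE * beta
        step = linalg.solve(A, grad, assume_a="pos")
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta, A


def _logistic_step(X_obs, y_obs, X_mis, rng, warm=None):
    if y_obs.min() == y_obs.max():  # single observed class
        return np.full(X_mis.shape[0], y_obs[0])
    beta_hat, A = _irls_logistic(X_obs, y_obs, beta0=warm)
    L = linalg.cholesky(A, lower=True)
    beta_star = _draw_mvn_from_precision(beta_hat, L, rng)
    p_mis = expit(np.clip(X_mis @ beta_star, -30, 30))
    return (rng.random(p_mis.size) < p_mis).astype(float), beta_hat


def _multinomial_step(X_obs, codes_obs, X_mis, n_classes, rng, warm=None):
    present = np.unique(codes_obs)
    if present.size == 1:
        return np.full(X_mis.shape[0], present[0], dtype=np.int64), None
    n, p = X_obs.shape
    K = n_classes
    Y = np.zeros((n, K))
    Y[np.arange(n), codes_obs] = 1.0

    def nll_grad(flat):
        B = np.zeros((p, K))
        B[:, 1:] = flat.reshape(p, K - 1)
        logits = X_obs @ B
        probs = softmax(logits, axis=1)
        nll = -np.sum(Y * (logits - linalg_logsumexp(logits)))
        G = X_obs.T @ (probs - Y)
        return nll / n, (G[:, 1:] / n).ravel()

    x0 = np.zeros(p * (K - 1)) if warm is None else warm
    res = optimize.minimize(
        nll_grad, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": 200, "ftol": 1e-9},
    )
    B = np.zeros((p, K))
    B[:, 1:] = res.x.reshape(p, K - 1)
    probs_mis = softmax(X_mis @ B, axis=1)
    u = rng.random(X_mis.shape[0])[:, None]
    draws = (probs_mis.cumsum(axis=1) < u).sum(axis=1)
    return np.clip(draws, 0, K - 1).astype(np.int64), res.x


def linalg_logsumexp(logits):
    m = logits.max(axis=1, keepdims=True)
    return m + np.log(np.exp(logits - m).sum(axis=1, keepdims=True))


class _Chain:
    """One MICE chain producing one completed copy."""

    def __init__(self, columns: dict, order: list, rng):
        self.columns = columns
        self.order = order
        self.rng = rng
        self._warm = {}

    def initialize(self):
        for name, col in self.columns.items():
            mis = col.missing
            if not mis.any():
                continue
            obs = col.values[~mis]
            col.values[mis] = self.rng.choice(obs, size=int(mis.sum()), replace=True)

    def _design_for(self, target: str):
        blocks = [np.ones((len(self.columns[target].values), 1))]
        for name, col in self.columns.items():
            if name == target:
                continue
            blocks.append(col.design_block())
        X = np.concatenate(blocks, axis=1)
        # standardize non-intercept columns for conditioning; drop constants
        mu = X[:, 1:].mean(axis=0)
        sd = X[:, 1:].std(axis=0)
        keep = sd > 1e-12
        X = np.concatenate([X[:, :1], (X[:, 1:][:, keep] - mu[keep]) / sd[keep]], axis=1)
        return X

    def sweep(self):
        for name in self.order:
            col = self.columns[name]
            mis = col.missing
            X = self._design_for(name)
            X_obs, X_mis = X[~mis], X[mis]
            if col.kind == "numeric":
                col.values[mis] = _pmm_step(X_obs, col.values[~mis], X_mis, self.rng)
            elif col.kind == "binary":
                out = _logistic_step(
                    X_obs, col.values[~mis], X_mis, self.rng,
                    warm=self._aligned_warm(name, X.shape[1]),
                )
                if isinstance(out, tuple):
                    col.values[mis], self._warm[name] = out
                else:
                    col.values[mis] = out
            else:
                draws, warm = _multinomial_step(
                    X_obs, col.values[~mis].astype(np.int64), X_mis,
                    len(col.categories), self.rng,
                    warm=self._aligned_warm(name, None),
                )
                col.values[mis] = draws
                if warm is not None:
                    self._warm[name] = warm

    def _aligned_warm(self, name, expected_len):
        w = self._warm.get(name)
        if w is None:
            return None
        if expected_len is not None and w.shape[0] != expected_len:
            return None
        return w


def mice_impute(
    table: pd.DataFrame,
    m: int = 20,
    iterations: int = 10,
    seed=None,
    variable_types: dict | None = None,
    ignore: tuple = ("participant_id",),
) -> ImputationSet:
    """Multiple imputation by chained equations.

    Parameters
    ----------
    table : cohort table; missing cells as NaN / None.
    m : number of completed copies (>= 2 for pooling).
    iterations : chained-equation sweeps per copy.
    seed : any ``numpy.random.default_rng`` seed.
    variable_types : optional {column: 'numeric'|'binary'|'categorical'}
        overriding dtype-based inference.
    ignore : columns copied through untouched (identifiers).

    Raises
    ------
    CarotidGsmError : a variable is 100% missing, or no complete
        variable exists to anchor the chains.
    """
    work = table.drop(columns=[c for c in ignore if c in table.columns])
    types = dict(infer_variable_types(work))
    if variable_types:
        types.update(variable_types)

    all_missing = [c for c in work.columns if work[c].isna().all()]
    if all_missing:
        raise CarotidGsmError(
            "cannot impute variables that are 100% missing: " + ", ".join(all_missing)
        )
    if not any(work[c].notna().all() for c in work.columns):
        raise CarotidGsmError("need at least one fully observed variable")

    with_missing = [c for c in work.columns if work[c].isna().any()]
    if not with_missing:
        copies = [table.copy() for _ in range(m)]
        return ImputationSet(copies=copies, m=m, iterations=iterations, seed=seed)

    order = sorted(with_missing, key=lambda c: work[c].isna().sum())
    master_rng = np.random.default_rng(seed)
    chain_seeds = master_rng.integers(0, 2**31 - 1, size=m)

    copies = []
    for j in range(m):
        rng = np.random.default_rng(int(chain_seeds[j]))
        columns = {c: _Column(work[c], types[c]) for c in work.columns}
        chain = _Chain(columns, order, rng)
        chain.initialize()
        for _ in range(iterations):
            chain.sweep()
        out = table.copy()
        for c in with_missing:
            out[c] = columns[c].to_series(table.index)
        copies.append(out)
    return ImputationSet(copies=copies, m=m, iterations=iterations, seed=seed)
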