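"""Missing-data handling: complete-case analysis and multiple imputation.

Two strategies are compared throughout the study:

* **CCA** — drop every record with any missing analysis variable.
* **MI** — multiple imputation by chained equations with univariate
  models chosen to be compatible with the two-stage Q-learning analysis
  model, followed by Rubin's-rules pooling of the per-imputation
  Q-learning estimates.

The chained-equations engine is *proper*: before every predictive draw
the regression coefficients (and, for the continuous outcome, the error
variance) are themselves drawn from their approximate posterior, so
between-imputation variance reflects model uncertainty.  Univariate
models (design columns beyond the intercept):

* ``Y``  — linear:    O1, A1, O2, A2, O1*A1, O2*A2, A1*A2
* ``O2`` — logistic:  O1, A1, A2, Y, O1*A1, A1*A2, Y*A2
* ``A2`` — logistic:  O1, A1, O2, Y, O1*A1, Y*O2, Y*A1

Interaction columns are recomputed passively from the current filled
values at every update.  Visit order is (O2, A2, Y), cycled
``n_cycles`` times per imputation; the initial fill samples from each
variable's observed values.  Binary imputations are drawn from the
logistic probability and coded back to {-1, +1}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .trial import COLUMNS, SeedLike, as_rng, validate_trial

__all__ = [
    "MIConfig",
    "PooledEstimate",
    "complete_case",
    "mice_impute",
    "pool_rubin",
    "default_m",
    "IMPUTATION_DESIGNS",
]

#: Ridge penalty used when a univariate model is singular or separated.
RIDGE_FALLBACK = 1e-2

#: Imputation-model design columns (beyond the intercept), per variable.
#: Product names mean elementwise products of the named columns.
IMPUTATION_DESIGNS: dict[str, tuple[str, ...]] = {
    "Y": ("O1", "A1", "O2", "A2", "O1*A1", "O2*A2", "A1*A2"),
    "O2": ("O1", "A1", "A2", "Y", "O1*A1", "A1*A2", "Y*A2"),
    "A2": ("O1", "A1", "O2", "Y", "O1*A1", "Y*O2", "Y*A1"),
}

VISIT_ORDER = ("O2", "A2", "Y")


@dataclass(frozen=True)
class MIConfig:
    """Multiple-imputation settings.

    ``m`` follows the rule of thumb "number of imputations >= percentage
    of incomplete cases": 20 for ~20% missingness, 40 for ~40%.
    """

    m: int = 20
    n_cycles: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"m must be >= 2, got {self.m}")
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")


def default_m(target_prop: float) -> int:
    """Imputation count for a missingness proportion (>= 100*prop)."""
    return max(2, int(round(100 * target_prop)))


def complete_case(data: pd.DataFrame) -> pd.DataFrame:
    """Records with all of O1, A1, O2, A2, Y observed, order preserved."""
    keep = data.loc[:, list(COLUMNS)].notna().all(axis=1)
    out = data.loc[keep]
    if len(out) == 0:
        raise ValueError("no complete cases: complete-case analysis infeasible")
    return out


def _design(df: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    """Intercept + named columns, with 'A*B' meaning a product column."""
    cols = [np.ones(len(df))]
    for name in columns:
        if "*" in name:
            a, b = name.split("*")
            cols.append(df[a].to_numpy(float) * df[b].to_numpy(float))
        else:
            cols.append(df[name].to_numpy(float))
    return np.column_stack(cols)


def _draw_linear(X, y, X_mis, rng) -> np.ndarray:
    """Bayesian linear-regression imputation draw.

    sigma^2 is drawn from its scaled inverse-chi-square posterior, beta
    from N(beta_hat, sigma^2 (X'X)^-1), and the prediction gets fresh
    Gaussian noise.  Singularity falls back to a ridge-stabilised fit.
    """
    n, k = X.shape
    XtX = X.T @ X
    try:
        L = np.linalg.cholesky(XtX)
    except np.linalg.LinAlgError:
        warnings.warn("singular linear imputation model; using ridge fallback")
        XtX = XtX + RIDGE_FALLBACK * n * np.eye(k)
        L = np.linalg.cholesky(XtX)
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - k, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    # beta* = beta_hat + sqrt(sigma2) * L^-T z  with L the Cholesky of X'X
    z = rng.standard_normal(k)
    beta = beta_hat + np.sqrt(sigma2) * np.linalg.solve(L.T, z)
    return X_mis @ beta + rng.normal(0.0, np.sqrt(sigma2), size=len(X_mis))


def _logistic_irls(X, y01, ridge: float = 0.0, max_iter: int = 30, tol: float = 1e-8):
    """Newton-Raphson logistic fit; returns (beta, cov) or raises
    LinAlgError / FloatingPointError on failure."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None]) + ridge * n * np.eye(k)
        grad = X.T @ (y01 - mu) - ridge * n * beta
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e3:
            raise FloatingPointError("logistic fit diverged")
        if np.max(np.abs(step)) < tol:
            break
    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None]) + ridge * n * np.eye(k)
    cov = np.linalg.inv(H)
    return beta, cov


def _draw_binary(X, y_pm1, X_mis, rng) -> np.ndarray:
    """Proper logistic imputation draw for a +/-1 coded variable."""
    y01 = (y_pm1 == 1.0).astype(float)
    try:
        beta, cov = _logistic_irls(X, y01)
    except (np.linalg.LinAlgError, FloatingPointError):
        warnings.warn(
            "separation or singularity in logistic imputation model; "
            "using ridge-stabilised fit"
        )
        beta, cov = _logistic_irls(X, y01, ridge=RIDGE_FALLBACK)
    # beta* ~ N(beta_hat, cov) via Cholesky; cov is SPD by construction
    L = np.linalg.cholesky(cov)
    beta_star = beta + L @ rng.standard_normal(len(beta))
    p = expit(X_mis @ beta_star)
    return np.where(rng.random(len(X_mis)) < p, 1.0, -1.0)


def mice_impute(data: pd.DataFrame, config: MIConfig) -> list[pd.DataFrame]:
    """Chained-equations multiple imputation; returns ``m`` completed tables.

    Observed cells are never altered.  A table with no missing cells
    returns ``m`` identical copies.  A variable with no observed values
    cannot be imputed and raises ValueError.
    """
    validate_trial(data)
    rng = as_rng(config.seed)
    work_cols = list(COLUMNS)
    base = data.loc[:, work_cols].astype(float)
    miss = {v: base[v].isna().to_numpy() for v in VISIT_ORDER}
    incomplete = [v for v in VISIT_ORDER if miss[v].any()]
    if not incomplete:
        return [base.copy() for _ in range(config.m)]
    for v in incomplete:
        if miss[v].all():
            raise ValueError(f"variable {v} has no observed values; cannot impute")

    observed_pool = {v: base.loc[~miss[v], v].to_numpy() for v in incomplete}

    # Work on a raw array for speed; column order follows COLUMNS.
    col_idx = {c: i for i, c in enumerate(work_cols)}
    values0 = base.to_numpy(dtype=float)
    design_terms = {
        v: [
            tuple(col_idx[c] for c in name.split("*"))
            for name in IMPUTATION_DESIGNS[v]
        ]
        for v in incomplete
    }

    def build_design(V: np.ndarray, rows: np.ndarray, v: str) -> np.ndarray:
        cols = [np.ones(len(rows))]
        for term in design_terms[v]:
            col = V[rows, term[0]]
            for j in term[1:]:
                col = col * V[rows, j]
            cols.append(col)
        return np.column_stack(cols)

    obs_rows = {v: np.flatnonzero(~miss[v]) for v in incomplete}
    mis_rows = {v: np.flatnonzero(miss[v]) for v in incomplete}

    completed: list[pd.DataFrame] = []
    for _ in range(config.m):
        V = values0.copy()
        for v in incomplete:  # initial fill: sample from observed values
            V[mis_rows[v], col_idx[v]] = rng.choice(
                observed_pool[v], size=len(mis_rows[v]), replace=True
            )
        for _cycle in range(config.n_cycles):
            for v in incomplete:
                X = build_design(V, obs_rows[v], v)
                X_mis = build_design(V, mis_rows[v], v)
                y = V[obs_rows[v], col_idx[v]]
                if v == "Y":
                    imputed = _draw_linear(X, y, X_mis, rng)
                else:
                    imputed = _draw_binary(X, y, X_mis, rng)
                V[mis_rows[v], col_idx[v]] = imputed
        completed.append(pd.DataFrame(V, columns=work_cols, index=base.index))
    return completed


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of m point estimates and variances."""

    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci_low: float
    ci_high: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def pool_rubin(points: Sequence[float], variances: Sequence[float]) -> PooledEstimate:
    """Rubin's rules for a scalar estimand.

    point = mean; within = mean variance; between = sample variance of
    the points; total = within + (1 + 1/m) between; df by the standard
    large-sample formula; 95% CI from the t distribution on df.
    """
    points = np.asarray(points, dtype=float)
    variances = np.asarray(variances, dtype=float)
    m = len(points)
    if m < 2:
        raise ValueError(f"Rubin pooling needs m >= 2 estimates, got {m}")
    if len(variances) != m:
        raise ValueError("points and variances must have equal length")
    if np.any(variances < 0):
        raise ValueError("variances must be non-negative")
    point = float(points.mean())
    within = float(variances.mean())
    between = float(points.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    if between > 0:
        df = (m - 1) * (1.0 + within / ((1.0 + 1.0 / m) * between)) ** 2
        tq = stats.t.ppf(0.975, df)
    else:
        df = np.inf
        tq = stats.norm.ppf(0.975)
    half = tq * np.sqrt(total)
    return PooledEstimate(
        point=point,
        within_var=within,
        between_var=between,
        total_var=total,
        df=float(df),
        ci_low=point - half,
        ci_high=point + half,
        m=m,
    )
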