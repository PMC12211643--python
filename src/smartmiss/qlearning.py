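"""Two-stage Q-learning by backward induction.

The Q-function at each stage is modelled linearly in history and
history-by-treatment interactions:

    Q2(H2, A2) = b20 + b21*O1 + b22*A1 + b23*O1*A1
                 + (p20 + p21*O2 + p22*A1) * A2
    Q1(H1, A1) = b10 + b11*O1 + (p10 + p11*O1) * A1

Stage 2 is fit first by ordinary least squares on the observed outcome.
Each record then receives the stage-1 pseudo-outcome — the fitted stage-2
model maximised over the stage-2 action:

    Yhat1 = b2' H2 + | p2' H2 |

(the stage-1 reward is identically zero in a design with a single
end-of-study outcome).  Stage 1 is an OLS of the pseudo-outcome on
(1, O1, A1, O1*A1).  The optimal decision rule at each stage is the sign
of the treatment-interaction part; an exact zero is the non-regular case
(no unique optimal action) and is broken deterministically towards +1
with a flag.

The stage-1 treatment main effect ``psi10`` is the primary estimand of
the simulation study; ``psi20`` is the secondary, stage-2 estimand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .trial import validate_trial

__all__ = [
    "Stage2Fit",
    "Stage1Fit",
    "QLearningFit",
    "RuleDecision",
    "fit_stage2",
    "pseudo_outcome",
    "fit_stage1",
    "optimal_rule",
    "qlearn",
]

#: Relative tolerance for rank detection in the QR solve.
RANK_RTOL = 1e-8

STAGE2_DESIGN = ("1", "O1", "A1", "O1A1", "A2", "O2A2", "A1A2")
STAGE1_DESIGN = ("1", "O1", "A1", "O1A1")


def _ols(X: np.ndarray, y: np.ndarray, columns: Sequence[str]):
    """QR-based least squares with an explicit rank check.

    Returns (coef, cov, residual_sd).  Rank deficiency raises ValueError
    naming the collinear columns (those whose R diagonal is below
    RANK_RTOL times the largest).
    """
    n, k = X.shape
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = diag < RANK_RTOL * diag.max() if diag.max() > 0 else np.ones(k, bool)
    if bad.any():
        names = [columns[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"design matrix is rank deficient in columns {names}")
    coef = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ coef
    dof = max(n - k, 1)
    sigma2 = float(resid @ resid) / dof
    Rinv = np.linalg.solve(R, np.eye(k))
    cov = sigma2 * (Rinv @ Rinv.T)
    return coef, cov, float(np.sqrt(sigma2))


@dataclass(frozen=True)
class Stage2Fit:
    """Stage-2 OLS fit: history effects ``beta2`` = (b20..b23), treatment
    interactions ``psi2`` = (p20, p21, p22), residual SD and the
    coefficient covariance in design order (1, O1, A1, O1A1, A2, O2A2,
    A1A2)."""

    beta2: np.ndarray
    psi2: np.ndarray
    residual_sd: float
    cov: np.ndarray

    @property
    def psi20(self) -> float:
        return float(self.psi2[0])


@dataclass(frozen=True)
class Stage1Fit:
    """Stage-1 OLS fit: ``beta1`` = (b10, b11), ``psi1`` = (p10, p11),
    coefficient covariance in design order (1, O1, A1, O1A1)."""

    beta1: np.ndarray
    psi1: np.ndarray
    cov: np.ndarray

    @property
    def psi10(self) -> float:
        return float(self.psi1[0])

    @property
    def psi10_se(self) -> float:
        """Model-based (OLS) standard error of psi10; treats the
        pseudo-outcome as fixed data, i.e. ignores stage-2 estimation
        uncertainty."""
        return float(np.sqrt(self.cov[2, 2]))


@dataclass(frozen=True)
class QLearningFit:
    stage2: Stage2Fit
    pseudo: np.ndarray
    stage1: Stage1Fit
    psi10_var: float

    @property
    def psi10(self) -> float:
        return self.stage1.psi10

    @property
    def psi20(self) -> float:
        return self.stage2.psi20

    @property
    def psi10_se(self) -> float:
        """Delta-method model SE of psi10 (see :func:`psi10_model_variance`)."""
        return float(np.sqrt(self.psi10_var))


class RuleDecision(NamedTuple):
    """An optimal-action decision: the chosen action and whether it was a
    tie (psi'h exactly zero — the non-regular case)."""

    action: int
    tie: bool


def _stage2_matrix(data: pd.DataFrame) -> np.ndarray:
    o1 = data["O1"].to_numpy(float)
    a1 = data["A1"].to_numpy(float)
    o2 = data["O2"].to_numpy(float)
    a2 = data["A2"].to_numpy(float)
    return np.column_stack(
        [np.ones(len(data)), o1, a1, o1 * a1, a2, o2 * a2, a1 * a2]
    )


def fit_stage2(data: pd.DataFrame) -> Stage2Fit:
    """OLS of Y on (1, O1, A1, O1A1, A2, O2A2, A1A2).

    All supplied records must have O2, A2 and Y observed; at least 7
    records spanning full column rank are required.
    """
    validate_trial(data)
    if data[["O2", "A2", "Y"]].isna().any().any():
        raise ValueError("stage-2 fit requires O2, A2 and Y observed for all records")
    if len(data) < len(STAGE2_DESIGN):
        raise ValueError(f"need at least {len(STAGE2_DESIGN)} records, got {len(data)}")
    X = _stage2_matrix(data)
    coef, cov, sd = _ols(X, data["Y"].to_numpy(float), STAGE2_DESIGN)
    return Stage2Fit(beta2=coef[:4], psi2=coef[4:], residual_sd=sd, cov=cov)


def pseudo_outcome(fit: Stage2Fit, data: pd.DataFrame) -> np.ndarray:
    """Stage-1 pseudo-outcome b2'H2 + |p2'H2| for each record.

    Requires O2 observed (H2 = (O1, A1, O2)); callers must resolve
    missingness first.
    """
    if data["O2"].isna().any():
        raise ValueError("pseudo-outcome requires O2 observed for every record")
    o1 = data["O1"].to_numpy(float)
    a1 = data["A1"].to_numpy(float)
    o2 = data["O2"].to_numpy(float)
    b = fit.beta2
    p = fit.psi2
    hist = b[0] + b[1] * o1 + b[2] * a1 + b[3] * o1 * a1
    return hist + np.abs(p[0] + p[1] * o2 + p[2] * a1)


def fit_stage1(pseudo: np.ndarray, data: pd.DataFrame) -> Stage1Fit:
    """OLS of the pseudo-outcome on (1, O1, A1, O1A1)."""
    pseudo = np.asarray(pseudo, dtype=float)
    if len(pseudo) != len(data):
        raise ValueError("pseudo-outcome length does not match data")
    if np.isnan(pseudo).any():
        raise ValueError("pseudo-outcome contains undefined values")
    o1 = data["O1"].to_numpy(float)
    a1 = data["A1"].to_numpy(float)
    X = np.column_stack([np.ones(len(data)), o1, a1, o1 * a1])
    coef, cov, _ = _ols(X, pseudo, STAGE1_DESIGN)
    return Stage1Fit(beta1=coef[:2], psi1=coef[2:], cov=cov)


def optimal_rule(psi: Sequence[float], history: Sequence[float]) -> RuleDecision:
    """sign(psi' h) with deterministic +1 tie-break at exactly zero."""
    value = float(np.dot(np.asarray(psi, float), np.asarray(history, float)))
    if value == 0.0:
        return RuleDecision(action=1, tie=True)
    return RuleDecision(action=1 if value > 0 else -1, tie=False)


def psi10_model_variance(
    stage2: Stage2Fit, stage1: Stage1Fit, data: pd.DataFrame
) -> float:
    """Delta-method variance of psi10 propagating stage-2 uncertainty.

    The naive stage-1 OLS variance is degenerate: the pseudo-outcome is a
    deterministic function of (O1, A1, O2) and, whenever the O2-by-A2
    interaction is absent, of (O1, A1) alone, leaving near-zero stage-1
    residuals.  The real sampling variability of psi10 enters through the
    estimated stage-2 coefficients inside ``b2'H2 + |p2'H2|``.  Writing
    psi10_hat = w' Yhat1(theta2_hat) with w the stage-1 projection
    weights, the gradient of Yhat1 w.r.t. theta2 = (b2, p2) is
    (H2_hist, sign(p2'H2) * H2), so

        Var(psi10_hat) ~= g' Cov(theta2_hat) g + sigma1^2 w'w,
        g = J' w.

    The absolute value is not differentiable at p2'H2 = 0, so this SE is
    anti-conservative in exactly non-regular configurations; the
    nonparametric bootstrap is the robust alternative.
    """
    o1 = data["O1"].to_numpy(float)
    a1 = data["A1"].to_numpy(float)
    o2 = data["O2"].to_numpy(float)
    n = len(data)
    X1 = np.column_stack([np.ones(n), o1, a1, o1 * a1])
    G = np.linalg.inv(X1.T @ X1)
    w = X1 @ G[:, 2]  # weights extracting the A1 coefficient
    p = stage2.psi2
    s = np.sign(p[0] + p[1] * o2 + p[2] * a1)
    J = np.column_stack([X1, s, s * o2, s * a1])  # d Yhat1 / d (b2, p2)
    g = J.T @ w
    var_stage2 = float(g @ stage2.cov @ g)
    # residual part of the stage-1 regression (usually negligible)
    var_stage1 = float(stage1.cov[2, 2])
    return var_stage2 + var_stage1


def qlearn(data: pd.DataFrame) -> QLearningFit:
    """Full two-stage Q-learning on a complete (or completed) table."""
    stage2 = fit_stage2(data)
    pseudo = pseudo_outcome(stage2, data)
    stage1 = fit_stage1(pseudo, data)
    var10 = psi10_model_variance(stage2, stage1, data)
    return QLearningFit(stage2=stage2, pseudo=pseudo, stage1=stage1, psi10_var=var10)
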