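"""Analytic true parameters and simulation performance measures.

True values of the stage-1 Q-learning parameters under a given
generative model are derived in closed form.  The population stage-1
pseudo-outcome mean in baseline cell (o1, a1) is

    f(o1, a1) = g1 + g2 o1 + g3 a1 + g4 o1 a1
                + p |g5 + g6 + g7 a1| + (1 - p) |g5 - g6 + g7 a1|

with p = P(O2 = 1 | o1, a1) = expit(delta1 o1 + delta2 a1): the
stage-2 history effects plus the responder-probability-weighted maximum
stage-2 treatment effect.  Projecting f onto the orthogonal stage-1
design (1, O1, A1, O1 A1) over the four equiprobable cells gives

    psi10_true = (1/4) sum a1 f(o1, a1)
    psi11_true = (1/4) sum o1 a1 f(o1, a1)

and the stage-2 truths are read off the outcome model directly:
(psi20, psi21, psi22) = (g5, g6, g7).

Performance of an estimator over replicated simulations is summarised
by signed bias, empirical SE (SD across replicates), MSE = variance +
bias^2, mean bootstrap SE, coverage of 95% intervals, and the Monte
Carlo standard error of the mean estimate (empirical SE / sqrt(reps)).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .trial import GenerativeParams, SeedLike, as_rng

__all__ = [
    "TruthSet",
    "PerformanceSummary",
    "derive_truth",
    "performance_summary",
    "bootstrap_se",
    "coverage",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TruthSet:
    """True stage-1 and stage-2 Q-learning parameters."""

    psi10: float
    psi11: float
    psi20: float
    psi21: float
    psi22: float


def derive_truth(params: GenerativeParams) -> TruthSet:
    """Closed-form true Q-learning parameters for a generative model."""
    g = params.gamma
    psi10 = 0.0
    psi11 = 0.0
    for o1, a1 in itertools.product((-1.0, 1.0), repeat=2):
        p = expit(params.delta1 * o1 + params.delta2 * a1)
        f = (
            g[0]
            + g[1] * o1
            + g[2] * a1
            + g[3] * o1 * a1
            + p * abs(g[4] + g[5] + g[6] * a1)
            + (1.0 - p) * abs(g[4] - g[5] + g[6] * a1)
        )
        psi10 += a1 * f / 4.0
        psi11 += o1 * a1 * f / 4.0
    return TruthSet(
        psi10=psi10, psi11=psi11, psi20=g[4], psi21=g[5], psi22=g[6]
    )


@dataclass(frozen=True)
class PerformanceSummary:
    """Monte Carlo performance of one estimator in one scenario cell."""

    n_reps: int
    bias: float
    empirical_se: float
    mse: float
    mc_error: float
    mean_bootstrap_se: Optional[float] = None
    coverage: Optional[float] = None

    @property
    def abs_bias(self) -> float:
        return abs(self.bias)


def performance_summary(
    estimates: Sequence[float],
    true_value: float,
    bootstrap_ses: Optional[Sequence[float]] = None,
    intervals: Optional[Sequence[tuple[float, float]]] = None,
) -> PerformanceSummary:
    """Summarise replicate estimates against the true value.

    bias = mean - truth (signed); empirical SE uses the n-1 divisor;
    mse = empirical variance + bias^2; mc_error = empirical SE /
    sqrt(n_reps).  Bootstrap SEs and CI coverage are included when the
    corresponding per-replicate inputs are supplied.
    """
    estimates = np.asarray(estimates, dtype=float)
    n_reps = len(estimates)
    if n_reps < 2:
        raise ValueError(f"need at least 2 estimates, got {n_reps}")
    bias = float(estimates.mean() - true_value)
    emp_var = float(estimates.var(ddof=1))
    emp_se = float(np.sqrt(emp_var))
    return PerformanceSummary(
        n_reps=n_reps,
        bias=bias,
        empirical_se=emp_se,
        mse=emp_var + bias**2,
        mc_error=emp_se / np.sqrt(n_reps),
        mean_bootstrap_se=(
            float(np.mean(bootstrap_ses)) if bootstrap_ses is not None else None
        ),
        coverage=(coverage(intervals, true_value) if intervals is not None else None),
    )


def bootstrap_se(
    data: pd.DataFrame,
    pipeline: Callable[[pd.DataFrame], float],
    B: int = 200,
    seed: SeedLike = 0,
    max_retries: int = 10,
) -> float:
    """Nonparametric bootstrap SE of a scalar statistic of a trial table.

    Records (participants) are resampled with replacement at the original
    size; ``pipeline`` — including any missing-data handling such as the
    complete-case subset or re-imputation — is re-run on each resample.
    A resample on which the pipeline fails (e.g. no complete cases) is
    redrawn, up to ``max_retries`` times each.
    """
    if B < 2:
        raise ValueError(f"B must be >= 2, got {B}")
    rng = as_rng(seed)
    n = len(data)
    values = np.empty(B)
    for b in range(B):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            resample = data.iloc[idx].reset_index(drop=True)
            try:
                values[b] = pipeline(resample)
                break
            except Exception as err:  # redraw: degenerate resample
                if attempt == max_retries:
                    raise RuntimeError(
                        f"bootstrap resample failed {max_retries + 1} times: {err}"
                    ) from err
                logger.warning("bootstrap resample %d failed (%s); redrawing", b, err)
    return float(np.std(values, ddof=1))


def coverage(intervals: Sequence[tuple[float, float]], true_value: float) -> float:
    """Fraction of intervals (low, high) containing the true value."""
    if len(intervals) < 1:
        raise ValueError("need at least one interval")
    hits = 0
    for low, high in intervals:
        if low > high:
            raise ValueError(f"malformed interval ({low}, {high})")
        hits += low <= true_value <= high
    return hits / len(intervals)
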