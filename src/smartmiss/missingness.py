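"""m-DAG missingness mechanisms for two-stage SMART data.

Seven scenarios impose missingness on ``O2``, ``A2`` and ``Y`` (``O1`` and
``A1`` are always complete).  Each scenario is a set of per-variable
logistic missingness models; the non-intercept log-odds are set from a
named association strength (odds ratio 1.6 = weak, 3 = strong) and the
intercepts are calibrated by bisection so that the scenario's primary
model hits a target marginal missingness proportion (20% or 40% in the
study grid).

Scenario summary (M_X = indicator that X is set missing):

* S1  — M_O2 and M_Y independent, intercept-only (MCAR).
* S2a — M_O2 intercept-only; logit P(M_Y) = a0 + a1*[A2 = 1];
        missing O2 forces A2 and Y missing.
* S2b — as S2a but logit P(M_O2) = a0 + a1*Y (outcome-dependent).
* S3a — logit P(M_O2) = a0 + a1*[O1 = 1] + a2*[A1 = 1]; propagation as S2.
* S3b — S3a plus + a3*Y in the M_O2 model.
* S4a — logit P(M_A2) = a0 + a1*[O2 = 1]; missing A2 forces Y missing;
        O2 fully observed.
* S4b — S4a plus + a2*Y in the M_A2 model.

Indicators ``[X = 1]`` are 0/1 (not +/-1); ``Y`` enters untransformed.
Missingness probabilities are always evaluated on the complete,
pre-deletion values.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .trial import GenerativeParams, SeedLike, as_rng, simulate_trial, validate_trial

__all__ = [
    "SCENARIOS",
    "STRENGTH_ODDS_RATIO",
    "MissingnessSpec",
    "calibrate_intercept",
    "calibrate_spec",
    "apply_missingness",
]

SCENARIOS = ("S1", "S2a", "S2b", "S3a", "S3b", "S4a", "S4b")

STRENGTH_ODDS_RATIO = {"weak": 1.6, "strong": 3.0}

# Linear predictors (without intercept) of each scenario's missingness
# models, as functions of the complete data and the association log-odds a.
# Indicator coding [X = 1] uses 0/1; Y is the raw outcome.


def _ind(x: pd.Series) -> np.ndarray:
    return (x.to_numpy(dtype=float) == 1.0).astype(float)


def _lp_zero(df: pd.DataFrame, a: float) -> np.ndarray:
    return np.zeros(len(df))


def _lp_a2(df: pd.DataFrame, a: float) -> np.ndarray:
    return a * _ind(df["A2"])


def _lp_y(df: pd.DataFrame, a: float) -> np.ndarray:
    return a * df["Y"].to_numpy(dtype=float)


def _lp_o1_a1(df: pd.DataFrame, a: float) -> np.ndarray:
    return a * _ind(df["O1"]) + a * _ind(df["A1"])


def _lp_o1_a1_y(df: pd.DataFrame, a: float) -> np.ndarray:
    return _lp_o1_a1(df, a) + _lp_y(df, a)


def _lp_o2(df: pd.DataFrame, a: float) -> np.ndarray:
    return a * _ind(df["O2"])


def _lp_o2_y(df: pd.DataFrame, a: float) -> np.ndarray:
    return _lp_o2(df, a) + _lp_y(df, a)


# scenario -> ordered dict of model name ("M_O2" | "M_A2" | "M_Y") -> lp fn.
_MODELS: dict[str, dict[str, Callable[[pd.DataFrame, float], np.ndarray]]] = {
    "S1": {"M_O2": _lp_zero, "M_Y": _lp_zero},
    "S2a": {"M_O2": _lp_zero, "M_Y": _lp_a2},
    "S2b": {"M_O2": _lp_y, "M_Y": _lp_a2},
    "S3a": {"M_O2": _lp_o1_a1},
    "S3b": {"M_O2": _lp_o1_a1_y},
    "S4a": {"M_A2": _lp_o2},
    "S4b": {"M_A2": _lp_o2_y},
}

#: The model whose intercept defines the scenario's headline missingness
#: proportion (responder status for S1-S3, stage-2 treatment for S4).
PRIMARY_MODEL = {
    "S1": "M_O2",
    "S2a": "M_O2",
    "S2b": "M_O2",
    "S3a": "M_O2",
    "S3b": "M_O2",
    "S4a": "M_A2",
    "S4b": "M_A2",
}


@dataclass(frozen=True)
class MissingnessSpec:
    """One missingness mechanism of the study grid.

    ``alpha0`` maps model name -> calibrated intercept; it is empty until
    :func:`calibrate_spec` freezes the intercepts.  ``strength`` must be
    ``"none"`` exactly for the covariate-free scenario S1.
    """

    scenario: str
    strength: str
    target_prop: float
    alpha0: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "S1":
            if self.strength != "none":
                raise ValueError("scenario S1 takes strength 'none'")
        elif self.strength not in STRENGTH_ODDS_RATIO:
            raise ValueError(
                f"strength must be 'weak' or 'strong' for {self.scenario}, "
                f"got {self.strength!r}"
            )
        if not 0.0 < self.target_prop < 1.0:
            raise ValueError(f"target_prop must be in (0,1), got {self.target_prop}")

    @property
    def association_log_odds(self) -> float:
        """log(OR) applied to every non-intercept coefficient."""
        if self.strength == "none":
            return 0.0
        return math.log(STRENGTH_ODDS_RATIO[self.strength])

    @property
    def model_names(self) -> tuple[str, ...]:
        return tuple(_MODELS[self.scenario])

    @property
    def primary_model(self) -> str:
        return PRIMARY_MODEL[self.scenario]

    @property
    def is_calibrated(self) -> bool:
        return all(name in self.alpha0 for name in self.model_names)

    def linear_predictor(self, model: str, data: pd.DataFrame) -> np.ndarray:
        """Non-intercept part of ``model``'s logit on complete data."""
        return _MODELS[self.scenario][model](data, self.association_log_odds)

    def with_alpha0(self, alpha0: dict[str, float]) -> "MissingnessSpec":
        return dataclasses.replace(self, alpha0=dict(alpha0))


def calibrate_intercept(
    spec: MissingnessSpec,
    params: GenerativeParams,
    target_prop: Optional[float] = None,
    n_calib: int = 200_000,
    seed: SeedLike = 0,
    tol: float = 0.005,
    model: Optional[str] = None,
    max_iter: int = 200,
) -> float:
    """Calibrate one missingness model's intercept by bisection.

    Finds alpha0 such that the mean missingness probability
    ``mean(expit(alpha0 + lp_i))`` over a fresh simulated trial of
    ``n_calib`` records equals ``target_prop`` (default: the spec's
    target).  The mean probability is strictly increasing in alpha0, so
    bisection on an expanding bracket always converges; covariate-free
    models reduce to the closed form ``logit(target_prop)``.
    """
    if target_prop is None:
        target_prop = spec.target_prop
    if not 0.0 < target_prop < 1.0:
        raise ValueError(f"target_prop must be in (0,1), got {target_prop}")
    model = model or spec.primary_model
    if model not in spec.model_names:
        raise ValueError(f"scenario {spec.scenario} has no model {model!r}")

    lp_fn = _MODELS[spec.scenario][model]
    if lp_fn is _lp_zero:
        return float(logit(target_prop))

    calib = simulate_trial(params, n_calib, as_rng(seed))
    lp = spec.linear_predictor(model, calib)

    def achieved(alpha0: float) -> float:
        return float(np.mean(expit(alpha0 + lp)))

    lo, hi = -20.0, 20.0
    f_lo, f_hi = achieved(lo), achieved(hi)
    if not (f_lo < target_prop < f_hi):
        raise RuntimeError(
            f"calibration bracket [{lo}, {hi}] does not straddle the target "
            f"({f_lo:.4f}, {f_hi:.4f} vs {target_prop})"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = achieved(mid)
        if abs(f_mid - target_prop) < min(tol, 1e-6) or hi - lo < 1e-12:
            return mid
        if f_mid < target_prop:
            lo = mid
        else:
            hi = mid
    last = 0.5 * (lo + hi)
    if abs(achieved(last) - target_prop) <= tol:
        return last
    raise RuntimeError(
        f"intercept calibration did not converge; last bracket [{lo}, {hi}]"
    )


def calibrate_spec(
    spec: MissingnessSpec,
    params: GenerativeParams,
    n_calib: int = 200_000,
    seed: SeedLike = 0,
    tol: float = 0.005,
) -> MissingnessSpec:
    """Return a copy of ``spec`` with every model's intercept calibrated.

    Each model of the scenario is calibrated to the same marginal
    ``target_prop``; the calibration sample is shared.
    """
    rng = as_rng(seed)
    calib_seed = rng.integers(2**31)
    alpha0 = {
        name: calibrate_intercept(
            spec, params, n_calib=n_calib, seed=int(calib_seed), tol=tol, model=name
        )
        for name in spec.model_names
    }
    return spec.with_alpha0(alpha0)


def apply_missingness(
    data: pd.DataFrame, spec: MissingnessSpec, seed: SeedLike
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impose the scenario's missingness on a complete trial table.

    Returns ``(masked, mask)`` where ``mask`` has 0/1 columns
    ``M_O2, M_A2, M_Y``.  Draws use the complete pre-deletion values;
    monotone propagation (missing O2 forces A2 and Y missing in S2/S3;
    missing A2 forces Y missing in S4) is applied after the draws.
    S1 draws M_O2 and M_Y independently with no propagation.
    """
    validate_trial(data, allow_missing=False)
    if not spec.is_calibrated:
        raise ValueError(
            f"spec for {spec.scenario} is not calibrated (alpha0 missing for "
            f"{[m for m in spec.model_names if m not in spec.alpha0]})"
        )
    rng = as_rng(seed)
    n = len(data)
    draws = {}
    for name in spec.model_names:
        p = expit(spec.alpha0[name] + spec.linear_predictor(name, data))
        draws[name] = (rng.random(n) < p).astype(int)

    m_o2 = draws.get("M_O2", np.zeros(n, dtype=int))
    m_a2 = draws.get("M_A2", np.zeros(n, dtype=int))
    m_y = draws.get("M_Y", np.zeros(n, dtype=int))

    scen = spec.scenario
    if scen in ("S2a", "S2b", "S3a", "S3b"):
        # thick arrows of the m-DAG: missing responder status hides the
        # stage-2 treatment and the outcome as well
        m_a2 = np.where(m_o2 == 1, 1, m_a2)
        m_y = np.where(m_o2 == 1, 1, m_y)
    elif scen in ("S4a", "S4b"):
        m_y = np.where(m_a2 == 1, 1, m_y)

    masked = data.copy()
    masked.loc[m_o2 == 1, "O2"] = np.nan
    masked.loc[m_a2 == 1, "A2"] = np.nan
    masked.loc[m_y == 1, "Y"] = np.nan
    mask = pd.DataFrame(
        {"M_O2": m_o2, "M_A2": m_a2, "M_Y": m_y}, index=data.index
    )
    return masked, mask
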