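"""Simulation of complete two-stage SMART trials.

A SMART (sequential multiple assignment randomised trial) randomises each
participant twice.  The generative model used throughout this package is a
simple two-stage, two-treatment design with binary baseline covariate,
binary interim responder status and a continuous end-of-study outcome:

* ``O1`` — baseline characteristic, P(O1 = 1) = 0.5, coded {-1, +1}
* ``A1`` — stage-1 treatment, randomised fairly, coded {-1, +1}
* ``O2`` — responder status after stage 1,
  P(O2 = 1 | O1, A1) = expit(delta1*O1 + delta2*A1)
* ``A2`` — stage-2 treatment, randomised fairly, coded {-1, +1}
* ``Y``  — continuous outcome,
  Y = g1 + g2*O1 + g3*A1 + g4*O1*A1 + g5*A2 + g6*O2*A2 + g7*A1*A2 + eps,
  eps ~ N(0, noise_sd^2)

Five named presets span the regularity spectrum of the stage-2 treatment
effect (from "no participant has a stage-2 effect" to "every participant
has a large effect"); they are the study conditions for the whole
missing-data simulation study in :mod:`smartmiss.study`.

Trials are plain :class:`pandas.DataFrame` objects with columns
``O1, A1, O2, A2, Y``; missing cells are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "COLUMNS",
    "GenerativeParams",
    "TreatmentEffectPreset",
    "table1_preset",
    "simulate_trial",
    "conditional_outcome_mean",
    "validate_trial",
    "read_trial",
    "write_trial",
]

#: Canonical column order of a trial table.
COLUMNS = ("O1", "A1", "O2", "A2", "Y")

#: Columns that are binary (+/-1 coded).
BINARY_COLUMNS = ("O1", "A1", "O2", "A2")

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence]


def as_rng(seed: SeedLike) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the trial generative model.

    Parameters
    ----------
    delta1, delta2
        Responder-model log-odds coefficients on ``O1`` and ``A1``.
    gamma
        The seven outcome-model coefficients ``(g1, ..., g7)`` multiplying
        ``1, O1, A1, O1*A1, A2, O2*A2, A1*A2`` respectively.
    noise_sd
        Standard deviation of the additive Gaussian outcome noise.
    """

    delta1: float
    delta2: float
    gamma: tuple[float, ...]
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        gamma = tuple(float(g) for g in self.gamma)
        if len(gamma) != 7:
            raise ValueError(f"gamma must have exactly 7 entries, got {len(gamma)}")
        object.__setattr__(self, "gamma", gamma)
        if not self.noise_sd > 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")


@dataclass(frozen=True)
class TreatmentEffectPreset:
    """A named treatment-effect setting (one row of the study design)."""

    setting_id: int
    params: GenerativeParams
    regularity_label: str


def _preset(setting_id: int, gamma: Sequence[float], label: str) -> TreatmentEffectPreset:
    return TreatmentEffectPreset(
        setting_id=setting_id,
        params=GenerativeParams(delta1=0.5, delta2=0.5, gamma=tuple(gamma)),
        regularity_label=label,
    )


# The five treatment-effect settings.  gamma = (g1..g7); all settings share
# delta1 = delta2 = 0.5 and unit outcome noise.
_PRESETS: dict[int, TreatmentEffectPreset] = {
    1: _preset(1, (0, 0, 0, 0, 0, 0, 0), "fully non-regular"),
    2: _preset(2, (0, 0, -0.5, 0, 0, 0, 1), "fully regular"),
    3: _preset(3, (0, 0, -0.5, 0, 0.5, 0, 0.5), "non-regular"),
    4: _preset(4, (0, 0, -0.5, 0, 0.5, 0, 0.49), "regular-close-to-non-regular"),
    5: _preset(5, (0, 0, -0.5, 0, 1, 0, 1), "non-regular"),
}


def table1_preset(setting_id: int) -> TreatmentEffectPreset:
    """Return the generative parameters of one of the five named settings.

    Raises
    ------
    ValueError
        If ``setting_id`` is not in 1..5.
    """
    try:
        return _PRESETS[int(setting_id)]
    except (KeyError, TypeError) as err:
        raise ValueError(
            f"unknown treatment-effect setting {setting_id!r}; expected 1..5"
        ) from err


def simulate_trial(params: GenerativeParams, n: int, seed: SeedLike) -> pd.DataFrame:
    """Simulate a fully observed two-stage SMART of ``n`` participants.

    ``O1``, ``A1`` and ``A2`` are fair +/-1 coin flips; ``O2`` follows the
    logistic responder model; ``Y`` is the linear outcome model plus
    N(0, noise_sd) noise.  Reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = as_rng(seed)
    o1 = rng.choice([-1.0, 1.0], size=n)
    a1 = rng.choice([-1.0, 1.0], size=n)
    p_resp = expit(params.delta1 * o1 + params.delta2 * a1)
    o2 = np.where(rng.random(n) < p_resp, 1.0, -1.0)
    # Stage-2 randomisation is fair in every (A1, O2) stratum, so a single
    # per-record fair draw is identical in distribution.
    a2 = rng.choice([-1.0, 1.0], size=n)
    g = params.gamma
    mu = (
        g[0]
        + g[1] * o1
        + g[2] * a1
        + g[3] * o1 * a1
        + g[4] * a2
        + g[5] * o2 * a2
        + g[6] * a1 * a2
    )
    y = mu + rng.normal(0.0, params.noise_sd, size=n)
    return pd.DataFrame({"O1": o1, "A1": a1, "O2": o2, "A2": a2, "Y": y})


def conditional_outcome_mean(params: GenerativeParams, o1, a1, o2, a2) -> float:
    """Noiseless mean of ``Y`` in the cell ``(o1, a1, o2, a2)``.

    All four arguments must be +/-1 (scalars or equal-length arrays).  This
    is the analytic oracle used by tests and by the truth derivation.
    """
    o1, a1, o2, a2 = (np.asarray(v, dtype=float) for v in (o1, a1, o2, a2))
    for name, v in zip(("o1", "a1", "o2", "a2"), (o1, a1, o2, a2)):
        if not np.all(np.isin(v, (-1.0, 1.0))):
            raise ValueError(f"{name} must be in {{-1, 1}}, got {v!r}")
    g = params.gamma
    mu = (
        g[0]
        + g[1] * o1
        + g[2] * a1
        + g[3] * o1 * a1
        + g[4] * a2
        + g[5] * o2 * a2
        + g[6] * a1 * a2
    )
    return float(mu) if mu.ndim == 0 else mu


def validate_trial(data: pd.DataFrame, allow_missing: bool = True) -> pd.DataFrame:
    """Check a trial table's schema and coding; return it unchanged.

    Binary columns must contain only {-1, +1} (and NaN when
    ``allow_missing``); ``O1`` and ``A1`` are always required complete.
    """
    missing_cols = [c for c in COLUMNS if c not in data.columns]
    if missing_cols:
        raise ValueError(f"trial table lacks columns {missing_cols}")
    if len(data) < 1:
        raise ValueError("trial table must have at least one record")
    for col in BINARY_COLUMNS:
        vals = data[col].to_numpy(dtype=float)
        ok = np.isin(vals, (-1.0, 1.0)) | np.isnan(vals)
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise ValueError(f"column {col} contains non +/-1 values {bad}")
    if data["O1"].isna().any() or data["A1"].isna().any():
        raise ValueError("O1 and A1 must be fully observed")
    if not allow_missing and data[list(COLUMNS)].isna().any().any():
        raise ValueError("trial table contains missing cells")
    return data


def write_trial(data: pd.DataFrame, path, zero_one: bool = False) -> None:
    """Write a trial table as CSV (header ``O1,A1,O2,A2,Y``, blanks for NaN).

    With ``zero_one=True`` the binary columns are exported in {0, 1} coding
    (-1 -> 0); the internal representation is always +/-1.
    """
    out = data.loc[:, list(COLUMNS)].copy()
    if zero_one:
        for col in BINARY_COLUMNS:
            out[col] = out[col].map({-1.0: 0.0, 1.0: 1.0})
    out.to_csv(path, index=False, na_rep="")


def read_trial(path, zero_one: bool = False) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trial` (lossless round-trip).

    With ``zero_one=True`` the file's binary columns are interpreted as
    {0, 1} and recoded to the internal +/-1 convention.  No silent recoding
    ever happens: without the flag, {0,1}-coded input fails validation.
    """
    data = pd.read_csv(path, usecols=list(COLUMNS))[list(COLUMNS)]
    data = data.astype(float)
    if zero_one:
        for col in BINARY_COLUMNS:
            data[col] = data[col].map({0.0: -1.0, 1.0: 1.0})
    return validate_trial(data)
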