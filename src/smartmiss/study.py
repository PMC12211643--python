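"""Factorial simulation study: scenario grid, cell runner, aggregation.

The full design crosses 5 treatment-effect settings with 26 missingness
mechanisms (scenario S1 at two proportions; scenarios S2a..S4b at two
association strengths and two proportions), 130 cells in all.  Each cell
is run for ``n_reps`` replicates of an ``n``-participant trial; each
replicate is simulated, masked, handled by complete-case analysis and/or
multiple imputation, and analysed by two-stage Q-learning; the stage-1
and stage-2 treatment effects are summarised against the analytic truth.

Seeding: every replicate draws four independent sub-streams (trial
generation, missingness, imputation, bootstrap) from
``SeedSequence([cell_root_seed, replicate_index])``, so any single
replicate is reconstructible and results are invariant to execution
order.  Missingness intercepts are calibrated once per
(setting, scenario, strength, proportion) on a fixed large sample whose
seed is a stable hash of those factors.

Bootstrap SEs and coverage are computed only for a designated subset of
cells by default (settings 1, 2, 4 under scenarios S1 and S2a) because
of their cost; a flag widens this.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import handling, metrics, missingness, qlearning, trial

__all__ = [
    "ScenarioCell",
    "StudyConfig",
    "enumerate_scenarios",
    "replicate_streams",
    "calibration_seed",
    "run_cell",
    "run_study",
    "load_config",
    "BOOTSTRAP_SUBSET_SETTINGS",
    "BOOTSTRAP_SUBSET_SCENARIOS",
]

logger = logging.getLogger(__name__)

BOOTSTRAP_SUBSET_SETTINGS = (1, 2, 4)
BOOTSTRAP_SUBSET_SCENARIOS = ("S1", "S2a")

RESULT_COLUMNS = [
    "setting", "scenario", "strength", "target_prop", "method", "estimand",
    "n", "n_reps", "n_failed", "root_seed", "true_value", "mean_estimate",
    "bias", "empirical_se", "mse", "mc_error", "mean_bootstrap_se", "coverage",
]


@dataclass(frozen=True)
class ScenarioCell:
    """One cell of the method-free simulation grid."""

    treatment_setting: int
    missing_scenario: str
    strength: str
    target_prop: float
    n: int = 500
    n_reps: int = 1000
    root_seed: int = 0

    def __post_init__(self) -> None:
        if self.treatment_setting not in range(1, 6):
            raise ValueError(f"treatment_setting must be 1..5, got {self.treatment_setting}")
        # delegate scenario/strength validation
        missingness.MissingnessSpec(
            self.missing_scenario, self.strength, self.target_prop
        )

    @property
    def cell_id(self) -> str:
        return (
            f"set{self.treatment_setting}_{self.missing_scenario}_"
            f"{self.strength}_p{int(round(100 * self.target_prop))}"
        )


def _stable_seed(*parts) -> int:
    """Deterministic sub-2^31 seed from arbitrary printable parts."""
    return zlib.crc32("|".join(str(p) for p in parts).encode()) % (2**31)


def calibration_seed(cell: ScenarioCell) -> int:
    """Fixed calibration-sample seed shared by all cells with the same
    (setting, scenario, strength, proportion)."""
    return _stable_seed(
        "calibration",
        cell.treatment_setting,
        cell.missing_scenario,
        cell.strength,
        cell.target_prop,
    )


def enumerate_scenarios(
    base_seed: int = 0, n: int = 500, n_reps: int = 1000
) -> list[ScenarioCell]:
    """The 130-cell grid in deterministic order.

    5 settings x (S1 x {20%, 40%} + 6 scenarios x {weak, strong} x
    {20%, 40%}) = 5 x 26 = 130.  Each cell's root seed is a stable hash
    of the base seed and the cell identifiers.
    """
    cells = []
    for setting in range(1, 6):
        for scenario in missingness.SCENARIOS:
            strengths = ("none",) if scenario == "S1" else ("weak", "strong")
            for strength, prop in itertools.product(strengths, (0.2, 0.4)):
                cells.append(
                    ScenarioCell(
                        treatment_setting=setting,
                        missing_scenario=scenario,
                        strength=strength,
                        target_prop=prop,
                        n=n,
                        n_reps=n_reps,
                        root_seed=_stable_seed(base_seed, setting, scenario, strength, prop),
                    )
                )
    return cells


def replicate_streams(root_seed: int, rep: int) -> dict[str, np.random.Generator]:
    """Independent generators for one replicate's four random components."""
    children = np.random.SeedSequence([root_seed, rep]).spawn(4)
    names = ("trial", "missingness", "imputation", "bootstrap")
    return {k: np.random.default_rng(s) for k, s in zip(names, children)}


def _cca_psi(masked: pd.DataFrame) -> qlearning.QLearningFit:
    return qlearning.qlearn(handling.complete_case(masked))


def _mi_fit(
    masked: pd.DataFrame,
    m: int,
    n_cycles: int,
    rng: np.random.Generator,
    boot_rng: Optional[np.random.Generator] = None,
    B: int = 200,
):
    """Impute, analyse each completed table, and Rubin-pool psi10/psi20.

    Per-imputation psi10 variances are model-based OLS by default; when
    ``boot_rng`` is given they come from a ``B``-resample nonparametric
    bootstrap of the Q-learning fit on each completed table.
    """
    seed = int(rng.integers(2**31))
    completed = handling.mice_impute(
        masked, handling.MIConfig(m=m, n_cycles=n_cycles, seed=seed)
    )
    fits = [qlearning.qlearn(c) for c in completed]
    p10 = [f.psi10 for f in fits]
    p20 = [f.psi20 for f in fits]
    if boot_rng is None:
        v10 = [f.psi10_var for f in fits]
    else:
        v10 = [
            metrics.bootstrap_se(
                c, lambda d: qlearning.qlearn(d).psi10, B=B, seed=boot_rng
            )
            ** 2
            for c in completed
        ]
    v20 = [float(f.stage2.cov[4, 4]) for f in fits]
    pooled10 = handling.pool_rubin(p10, v10)
    pooled20 = handling.pool_rubin(p20, v20)
    return pooled10, pooled20


def run_cell(
    cell: ScenarioCell,
    mi_config: Optional[handling.MIConfig] = None,
    methods: Sequence[str] = ("CCA", "MI"),
    bootstrap: bool | str = "auto",
    B: int = 200,
    n_calib: int = 200_000,
    max_fail_frac: float = 0.01,
) -> pd.DataFrame:
    """Run one grid cell; returns one row per (method x estimand).

    ``bootstrap="auto"`` enables bootstrap SEs and coverage only in the
    designated subset of cells.  Replicate-level failures are logged and
    counted; more than ``max_fail_frac`` of replicates failing aborts
    the cell.
    """
    preset = trial.table1_preset(cell.treatment_setting)
    truth = metrics.derive_truth(preset.params)
    spec = missingness.MissingnessSpec(
        cell.missing_scenario, cell.strength, cell.target_prop
    )
    spec = missingness.calibrate_spec(
        spec, preset.params, n_calib=n_calib, seed=calibration_seed(cell)
    )
    if bootstrap == "auto":
        do_boot = (
            cell.treatment_setting in BOOTSTRAP_SUBSET_SETTINGS
            and cell.missing_scenario in BOOTSTRAP_SUBSET_SCENARIOS
        )
    else:
        do_boot = bool(bootstrap)
    m = mi_config.m if mi_config is not None else handling.default_m(cell.target_prop)
    n_cycles = mi_config.n_cycles if mi_config is not None else 10

    est: dict[tuple[str, str], list[float]] = {
        (meth, psi): [] for meth in methods for psi in ("psi10", "psi20")
    }
    boot_ses: dict[str, list[float]] = {meth: [] for meth in methods}
    cis: dict[str, list[tuple[float, float]]] = {meth: [] for meth in methods}
    n_failed = 0

    for rep in range(cell.n_reps):
        streams = replicate_streams(cell.root_seed, rep)
        try:
            complete = trial.simulate_trial(preset.params, cell.n, streams["trial"])
            masked, _ = missingness.apply_missingness(
                complete, spec, streams["missingness"]
            )
            if "CCA" in methods:
                fit = _cca_psi(masked)
                est[("CCA", "psi10")].append(fit.psi10)
                est[("CCA", "psi20")].append(fit.psi20)
                if do_boot:
                    se = metrics.bootstrap_se(
                        masked,
                        lambda d: _cca_psi(d).psi10,
                        B=B,
                        seed=streams["bootstrap"],
                    )
                    tq = stats.t.ppf(0.975, B - 1)
                    boot_ses["CCA"].append(se)
                    cis["CCA"].append((fit.psi10 - tq * se, fit.psi10 + tq * se))
            if "MI" in methods:
                pooled10, pooled20 = _mi_fit(
                    masked,
                    m,
                    n_cycles,
                    streams["imputation"],
                    boot_rng=streams["bootstrap"] if do_boot else None,
                    B=B,
                )
                est[("MI", "psi10")].append(pooled10.point)
                est[("MI", "psi20")].append(pooled20.point)
                if do_boot:
                    boot_ses["MI"].append(pooled10.se)
                    cis["MI"].append((pooled10.ci_low, pooled10.ci_high))
        except Exception as err:
            n_failed += 1
            logger.warning("cell %s replicate %d failed: %s", cell.cell_id, rep, err)

    if n_failed > max_fail_frac * cell.n_reps:
        raise RuntimeError(
            f"cell {cell.cell_id}: {n_failed}/{cell.n_reps} replicates failed"
        )

    rows = []
    for meth in methods:
        for psi, true_value in (("psi10", truth.psi10), ("psi20", truth.psi20)):
            values = est[(meth, psi)]
            with_boot = do_boot and psi == "psi10"
            summ = metrics.performance_summary(
                values,
                true_value,
                bootstrap_ses=boot_ses[meth] if with_boot else None,
                intervals=cis[meth] if with_boot else None,
            )
            rows.append(
                {
                    "setting": cell.treatment_setting,
                    "scenario": cell.missing_scenario,
                    "strength": cell.strength,
                    "target_prop": cell.target_prop,
                    "method": meth,
                    "estimand": psi,
                    "n": cell.n,
                    "n_reps": summ.n_reps,
                    "n_failed": n_failed,
                    "root_seed": cell.root_seed,
                    "true_value": true_value,
                    "mean_estimate": true_value + summ.bias,
                    "bias": summ.bias,
                    "empirical_se": summ.empirical_se,
                    "mse": summ.mse,
                    "mc_error": summ.mc_error,
                    "mean_bootstrap_se": summ.mean_bootstrap_se,
                    "coverage": summ.coverage,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a (possibly filtered / scaled-down) study run."""

    settings: tuple[int, ...] = (1, 2, 3, 4, 5)
    scenarios: tuple[str, ...] = missingness.SCENARIOS
    strengths: tuple[str, ...] = ("none", "weak", "strong")
    target_props: tuple[float, ...] = (0.2, 0.4)
    methods: tuple[str, ...] = ("CCA", "MI")
    n: int = 500
    n_reps: int = 1000
    base_seed: int = 0
    n_cycles: int = 10
    m_override: Optional[int] = None
    bootstrap: bool | str = "auto"
    B: int = 200
    outdir: str = "study_results"
    figures: bool = True

    def filter_cells(self) -> list[ScenarioCell]:
        cells = [
            c
            for c in enumerate_scenarios(self.base_seed, self.n, self.n_reps)
            if c.treatment_setting in self.settings
            and c.missing_scenario in self.scenarios
            and c.strength in self.strengths
            and c.target_prop in self.target_props
        ]
        if not cells:
            raise ValueError("study configuration selects no scenario cells")
        return cells


def load_config(path) -> StudyConfig:
    """Read a StudyConfig from a YAML mapping (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("settings", "scenarios", "strengths", "target_props", "methods"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return StudyConfig(**raw)


def _bias_figure(results: pd.DataFrame, setting: int, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = results[
        (results["setting"] == setting) & (results["estimand"] == "psi10")
    ].copy()
    if sub.empty:
        return
    sub["mechanism"] = (
        sub["scenario"]
        + sub["strength"].map({"none": "", "weak": " wk", "strong": " st"})
        + " "
        + (100 * sub["target_prop"]).astype(int).astype(str)
        + "%"
    )
    fig, ax = plt.subplots(figsize=(10, 4))
    mechanisms = sorted(sub["mechanism"].unique())
    x = np.arange(len(mechanisms))
    width = 0.38
    for off, method in ((-width / 2, "CCA"), (width / 2, "MI")):
        vals = [
            sub[(sub["mechanism"] == mech) & (sub["method"] == method)]["bias"].abs().mean()
            for mech in mechanisms
        ]
        ax.bar(x + off, vals, width, label=method)
    ax.set_xticks(x, mechanisms, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("|bias| of psi10")
    ax.set_title(f"Treatment effect setting {setting}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_study(config: StudyConfig) -> pd.DataFrame:
    """Run the configured grid; write per-cell and aggregate results.

    Per-cell outputs under ``<outdir>/cells/`` make the run resumable:
    a cell whose results file already exists is loaded, not re-run.
    Returns the long-format results table (also written to
    ``<outdir>/results.csv``).
    """
    outdir = Path(config.outdir)
    celldir = outdir / "cells"
    celldir.mkdir(parents=True, exist_ok=True)
    mi_config = (
        handling.MIConfig(m=config.m_override, n_cycles=config.n_cycles)
        if config.m_override
        else None
    )
    frames = []
    for cell in config.filter_cells():
        cell_path = celldir / f"{cell.cell_id}.csv"
        if cell_path.exists():
            logger.info("cell %s already done; loading", cell.cell_id)
            frames.append(pd.read_csv(cell_path))
            continue
        logger.info("running cell %s", cell.cell_id)
        mi = mi_config or handling.MIConfig(
            m=handling.default_m(cell.target_prop), n_cycles=config.n_cycles
        )
        rows = run_cell(
            cell,
            mi_config=mi,
            methods=config.methods,
            bootstrap=config.bootstrap,
            B=config.B,
        )
        rows.to_csv(cell_path, index=False)
        # round-trip through the cell file so fresh and resumed runs carry
        # identical dtypes
        frames.append(pd.read_csv(cell_path))
    results = pd.concat(frames, ignore_index=True)
    results = results.sort_values(
        ["setting", "scenario", "strength", "target_prop", "method", "estimand"],
        kind="mergesort",
    ).reset_index(drop=True)
    results.to_csv(outdir / "results.csv", index=False)
    if config.figures:
        for setting in sorted(results["setting"].unique()):
            _bias_figure(results, setting, outdir / f"bias_setting{setting}.png")
    return results
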