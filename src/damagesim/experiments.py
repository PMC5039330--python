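"""Replicate orchestration: sweeps over delta_t x alpha x scenario.

Each grid cell is run for a number of independent seeded replicates; per-cell
seeds are derived from the master seed with :class:`numpy.random.SeedSequence`
spawn keys, so results are independent of execution order and reproducible
across platforms.  Results come back as tidy tables (one row per replicate)
together with aggregated per-cell summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import ExtinctionError
from .scenarios import SCENARIO_LABELS, build_scenario, run_enrichment

__all__ = [
    "DEFAULT_DELTA_T_GRID",
    "DEFAULT_ALPHA_GRID",
    "SweepSpec",
    "SweepResult",
    "run_sweep",
    "replicate_seed",
    "summarize_constant_environments",
    "summarize_enrichment_scenarios",
]

#: Relaxation times examined in the study design.
DEFAULT_DELTA_T_GRID = (0.01, 0.05, 0.1, 0.4, 0.8, 1.0)
#: Hill steepnesses examined in the study design.
DEFAULT_ALPHA_GRID = (2.0, 4.0, 10.0)

_REPLICATE_COLUMNS = [
    "scenario",
    "delta_t",
    "alpha",
    "replicate",
    "seed",
    "status",
    "mean_g",
    "var_g",
    "mean_D",
    "var_D",
    "selective_deaths",
]


@dataclass(frozen=True)
class SweepSpec:
    """Full description of a sweep experiment."""

    scenarios: tuple[str, ...] = ("reference",)
    delta_t_grid: tuple[float, ...] = DEFAULT_DELTA_T_GRID
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    replicates: int = 100
    N: int = 1000
    generations: int = 1000
    burn_in: int | None = None
    master_seed: int = 0
    overrides: tuple[tuple[str, object], ...] = ()
    max_attempt_factor: int = 1000

    def __post_init__(self) -> None:
        if not self.scenarios or not self.delta_t_grid or not self.alpha_grid:
            raise ValueError("scenario and parameter grids must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = set(self.scenarios) - set(SCENARIO_LABELS)
        if unknown:
            raise ValueError(f"unknown scenario labels: {sorted(unknown)}")

    def cells(self) -> Iterable[tuple[int, str, float, float]]:
        """Deterministic enumeration of grid cells with their indices."""
        i = 0
        for label in self.scenarios:
            for dt in self.delta_t_grid:
                for alpha in self.alpha_grid:
                    yield i, label, float(dt), float(alpha)
                    i += 1


def replicate_seed(master_seed: int, cell_index: int, replicate: int) -> np.random.SeedSequence:
    """Seed for one replicate of one grid cell, stable across platforms and
    independent of execution order."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(cell_index, replicate))


@dataclass
class SweepResult:
    """Tidy per-replicate table plus its aggregation and provenance."""

    spec: SweepSpec
    replicates: pd.DataFrame

    @property
    def aggregate(self) -> pd.DataFrame:
        """Across-replicate summary per (scenario, delta_t, alpha).

        ``mean_g``/``mean_D`` columns hold the across-replicate mean and
        variance of the final population means; death counts are summed and
        averaged.  Extinct replicates are excluded from trait summaries and
        counted in ``n_extinct``.
        """
        df = self.replicates
        ok = df[df["status"] == "ok"]
        grouped = ok.groupby(["scenario", "delta_t", "alpha"], sort=True)
        agg = grouped.agg(
            n_replicates=("replicate", "size"),
            mean_mean_g=("mean_g", "mean"),
            var_mean_g=("mean_g", "var"),
            mean_mean_D=("mean_D", "mean"),
            var_mean_D=("mean_D", "var"),
            mean_within_var_g=("var_g", "mean"),
            mean_within_var_D=("var_D", "mean"),
            mean_selective_deaths=("selective_deaths", "mean"),
            total_selective_deaths=("selective_deaths", "sum"),
        )
        n_ext = (
            df.assign(ext=(df["status"] != "ok").astype(int))
            .groupby(["scenario", "delta_t", "alpha"], sort=True)["ext"]
            .sum()
            .rename("n_extinct")
        )
        return agg.join(n_ext).reset_index()

    def manifest(self) -> dict:
        """Provenance record: full spec, seed derivation and package version."""
        from . import __version__

        spec = asdict(self.spec)
        spec["overrides"] = dict(self.spec.overrides)
        return {
            "package": "damagesim",
            "version": __version__,
            "seed_derivation": "SeedSequence(master_seed, spawn_key=(cell_index, replicate))",
            "spec": spec,
        }


def run_sweep(spec: SweepSpec, progress: bool = False) -> SweepResult:
    """Run every (scenario, delta_t, alpha) cell for ``spec.replicates``
    independent seeded replicates.

    Extinction of a replicate is recorded in its ``status`` column rather
    than raised, so a sweep always completes.
    """
    rows = []
    cells = list(spec.cells())
    iterator = cells
    if progress:
        from tqdm import tqdm

        iterator = tqdm(cells, desc="sweep cells")
    overrides = dict(spec.overrides)
    for cell_index, label, dt, alpha in iterator:
        scenario = build_scenario(label, delta_t=dt, alpha=alpha, overrides=overrides)
        for rep in range(spec.replicates):
            ss = replicate_seed(spec.master_seed, cell_index, rep)
            rng = np.random.default_rng(ss)
            row = {
                "scenario": label,
                "delta_t": dt,
                "alpha": alpha,
                "replicate": rep,
                "seed": int(ss.entropy),
                "status": "ok",
                "mean_g": np.nan,
                "var_g": np.nan,
                "mean_D": np.nan,
                "var_D": np.nan,
                "selective_deaths": np.nan,
            }
            try:
                res = run_enrichment(
                    scenario,
                    N=spec.N,
                    generations=spec.generations,
                    rng=rng,
                    burn_in=spec.burn_in,
                    max_attempt_factor=spec.max_attempt_factor,
                )
            except ExtinctionError as err:
                row["status"] = f"extinct@{err.generation}"
            else:
                final = res.final
                row.update(
                    mean_g=final["mean_g"],
                    var_g=final["var_g"],
                    mean_D=final["mean_D"],
                    var_D=final["var_D"],
                    selective_deaths=final["selective_deaths"],
                )
            rows.append(row)
    return SweepResult(spec=spec, replicates=pd.DataFrame(rows, columns=_REPLICATE_COLUMNS))


def _require_scenarios(df: pd.DataFrame, labels: Sequence[str]) -> None:
    missing = [s for s in labels if s not in set(df["scenario"])]
    if missing:
        raise ValueError(f"sweep result does not cover scenario(s): {missing}")


def summarize_constant_environments(result: SweepResult) -> pd.DataFrame:
    """Constant-environment summary: per (environment, delta_t, alpha)
    across-replicate mean/variance of final mean growth, plus a pooled row
    per environment (grand mean and variance over all delta_t, alpha and
    replicates).

    Single-replicate cells report variance as NaN (not zero).
    """
    labels = [s for s in ("constant_1.0", "constant_2.0") if s in set(result.spec.scenarios)]
    _require_scenarios(result.replicates, labels or ["constant_1.0", "constant_2.0"])
    ok = result.replicates.query("status == 'ok'")
    ok = ok[ok["scenario"].isin(labels)]
    if ok.empty:
        raise ValueError("no surviving constant-environment replicates to summarise")
    per_cell = (
        ok.groupby(["scenario", "delta_t", "alpha"])
        .agg(n=("mean_g", "size"), mean_growth=("mean_g", "mean"), var_growth=("mean_g", "var"))
        .reset_index()
    )
    pooled = (
        ok.groupby("scenario")
        .agg(n=("mean_g", "size"), mean_growth=("mean_g", "mean"), var_growth=("mean_g", "var"))
        .reset_index()
        .assign(delta_t=np.nan, alpha=np.nan)
    )
    out = pd.concat([per_cell, pooled], ignore_index=True)
    return out[["scenario", "delta_t", "alpha", "n", "mean_growth", "var_growth"]]


def summarize_enrichment_scenarios(result: SweepResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Growth and damage summaries for enrichment scenarios.

    Returns ``(growth, damage)`` tables per (scenario, delta_t, alpha):
    across-replicate mean final growth / mean final damage, their
    across-replicate variances, and the mean selective-death count (the
    inverse point-size channel of the result figures).
    """
    labels = [s for s in result.spec.scenarios if not s.startswith("constant")]
    if not labels:
        raise ValueError("sweep result contains no enrichment scenarios")
    _require_scenarios(result.replicates, labels)
    ok = result.replicates.query("status == 'ok'")
    ok = ok[ok["scenario"].isin(labels)]
    keys = ["scenario", "delta_t", "alpha"]
    growth = (
        ok.groupby(keys)
        .agg(
            n=("mean_g", "size"),
            mean_growth=("mean_g", "mean"),
            var_growth=("mean_g", "var"),
            mean_selective_deaths=("selective_deaths", "mean"),
        )
        .reset_index()
    )
    damage = (
        ok.groupby(keys)
        .agg(
            n=("mean_D", "size"),
            mean_damage=("mean_D", "mean"),
            var_damage=("mean_D", "var"),
            mean_selective_deaths=("selective_deaths", "mean"),
        )
        .reset_index()
    )
    return growth, damage
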