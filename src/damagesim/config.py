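"""Run configuration: a strict, round-trippable YAML schema.

A :class:`RunConfig` bundles the sweep design (scenarios, grids, replicate
count, population size, generations, master seed) with model-parameter
overrides applied to every scenario.  Unknown keys are rejected by name so
typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .experiments import DEFAULT_ALPHA_GRID, DEFAULT_DELTA_T_GRID, SweepSpec
from .model import ModelParams
from .scenarios import SCENARIO_LABELS

__all__ = ["RunConfig", "load_config", "save_config"]

#: ModelParams fields that may be overridden from a config file.  K is
#: excluded because scenarios anchor it to the ancestral equilibrium.
_OVERRIDABLE = tuple(
    f.name for f in dataclasses.fields(ModelParams) if f.name not in ("g_max", "g_span", "K")
)


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with study defaults for omitted fields."""

    scenarios: tuple[str, ...] = ("reference",)
    delta_t_grid: tuple[float, ...] = DEFAULT_DELTA_T_GRID
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    replicates: int = 100
    N: int = 1000
    generations: int = 1000
    burn_in: int | None = None
    master_seed: int = 0
    model: dict[str, Any] = field(default_factory=dict)
    out_dir: str = "results"
    log_trajectory: bool = False
    verbosity: int = 1

    def __post_init__(self) -> None:
        unknown = set(self.scenarios) - set(SCENARIO_LABELS)
        if unknown:
            raise ValueError(f"unknown scenario labels: {sorted(unknown)}")
        bad = set(self.model) - set(_OVERRIDABLE)
        if bad:
            raise ValueError(
                f"unknown or non-overridable model key(s): {sorted(bad)}; "
                f"allowed: {sorted(_OVERRIDABLE)}"
            )
        # Fail fast on invalid parameter values.
        ModelParams(**self.model)
        if self.replicates < 1 or self.N < 1 or self.generations < 0:
            raise ValueError("replicates and N must be >= 1, generations >= 0")

    def sweep_spec(self) -> SweepSpec:
        return SweepSpec(
            scenarios=tuple(self.scenarios),
            delta_t_grid=tuple(self.delta_t_grid),
            alpha_grid=tuple(self.alpha_grid),
            replicates=self.replicates,
            N=self.N,
            generations=self.generations,
            burn_in=self.burn_in,
            master_seed=self.master_seed,
            overrides=tuple(sorted(self.model.items())),
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["scenarios"] = list(self.scenarios)
        d["delta_t_grid"] = list(self.delta_t_grid)
        d["alpha_grid"] = list(self.alpha_grid)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config file; omitted fields take the study
    defaults (N=1000, 1000 generations, 100 replicates, D_max=5, R_max=5,
    mutation scale 0.05, the standard delta_t and alpha grids)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("scenarios", "delta_t_grid", "alpha_grid"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back to YAML; ``load_config`` of the result is
    identical to ``config``."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
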