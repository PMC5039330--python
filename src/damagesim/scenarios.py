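"""Built-in simulation scenarios and the environmental-enrichment protocol.

An enrichment scenario pairs an ancestral environment (maximum growth rate
1.0) with an enriched one (maximum growth rate 2.0).  The population first
equilibrates ancestrally; the ceiling is then raised instantaneously and
evolution continues.  The damage tolerance K is set in the ancestral
environment (half the maximal ancestral equilibrium damage) and stays fixed
after enrichment, and the repair physiology keeps its ancestral trade-off
span: raising the environmental ceiling does not change how the organism
allocates resources between repair and growth.  The escape scenarios relax
exactly one constraint in the enriched environment:

- ``damage_tolerance``: K raised from D_eq(1)/2 to D_eq(1)/1.1,
- ``cheap_repair``: repair–growth trade-off slope lowered from 1 to 0.25,
- ``damage_reduction``: damage rate D_max lowered from 5 to 2.

``constant_1.0`` and ``constant_2.0`` use a single environment throughout
(no switch) and anchor K to their own maximal equilibrium damage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .engine import initialize_ancestral_population, run_generations
from .model import ModelParams, equilibrium_damage

__all__ = [
    "Scenario",
    "EnrichmentResult",
    "SCENARIO_LABELS",
    "build_scenario",
    "run_enrichment",
]

SCENARIO_LABELS = (
    "reference",
    "damage_tolerance",
    "cheap_repair",
    "damage_reduction",
    "constant_1.0",
    "constant_2.0",
)

#: K divisors relative to the maximal ancestral equilibrium damage.
_K_DIVISOR_REFERENCE = 2.0
_K_DIVISOR_TOLERANT = 1.1


@dataclass(frozen=True)
class Scenario:
    """A labelled (ancestral, enriched) pair of model parameterisations."""

    label: str
    ancestral: ModelParams
    enriched: ModelParams

    @property
    def is_constant(self) -> bool:
        """True for single-environment scenarios (no enrichment switch)."""
        return self.label.startswith("constant")


def build_scenario(
    label: str,
    delta_t: float = 0.1,
    alpha: float = 4.0,
    overrides: Mapping[str, Any] | None = None,
) -> Scenario:
    """Construct one of the built-in scenarios.

    ``overrides`` is applied to both environments before the enriched-side
    modification dictated by the label (useful for e.g. ``R_min`` or
    ``mutation_mode``).  ``delta_t`` and ``alpha`` are the swept parameters.
    """
    if label not in SCENARIO_LABELS:
        raise ValueError(f"unknown scenario label {label!r}; choose from {SCENARIO_LABELS}")
    common: dict[str, Any] = dict(delta_t=delta_t, alpha=alpha)
    common.update(overrides or {})
    common.pop("K", None)  # K is anchored by the scenario, never overridden

    if label == "constant_1.0":
        env = ModelParams(g_max=1.0, **common)
        return Scenario(label, env, env)
    if label == "constant_2.0":
        env = ModelParams(g_max=2.0, **common)
        return Scenario(label, env, env)

    ancestral = ModelParams(g_max=1.0, **common)
    # The enriched environment raises the growth ceiling but keeps the
    # ancestral repair span and damage tolerance.
    enriched = ancestral.with_(g_max=2.0, g_span=ancestral.g_span)
    if label == "damage_tolerance":
        k_tolerant = float(equilibrium_damage(ancestral.g_span, ancestral)) / _K_DIVISOR_TOLERANT
        enriched = enriched.with_(K=k_tolerant)
    elif label == "cheap_repair":
        enriched = enriched.with_(repair_slope=0.25)
    elif label == "damage_reduction":
        enriched = enriched.with_(D_max=2.0)
    return Scenario(label, ancestral, enriched)


@dataclass
class EnrichmentResult:
    """Outcome of one scenario run: trajectory plus final-state summary."""

    scenario: Scenario
    trajectory: pd.DataFrame
    final: dict[str, float]


def run_enrichment(
    scenario: Scenario,
    N: int = 1000,
    generations: int = 1000,
    rng: np.random.Generator | int | None = None,
    burn_in: int | None = None,
    record_every: int = 0,
    max_attempt_factor: int = 1000,
) -> EnrichmentResult:
    """Run the enrichment protocol for one scenario.

    Equilibrates under the ancestral environment for ``burn_in`` generations
    (default: ``generations`` for enrichment scenarios, 0 for constant
    ones), switches to the enriched environment, and evolves onward for
    ``generations`` generations.  Selective deaths are counted from the
    switch onward.  The trajectory covers the post-switch phase, starting
    at generation 0 (the state at the moment of the switch).
    """
    if N <= 0 or generations < 0:
        raise ValueError("N must be > 0 and generations >= 0")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if burn_in is None:
        burn_in = 0 if scenario.is_constant else generations
    pop = initialize_ancestral_population(
        scenario.ancestral, N, burn_in=burn_in, rng=rng, max_attempt_factor=max_attempt_factor
    )
    pop, traj = run_generations(
        pop,
        scenario.enriched,
        generations,
        rng,
        record_every=record_every,
        max_attempt_factor=max_attempt_factor,
    )
    return EnrichmentResult(scenario=scenario, trajectory=traj, final=pop.summary())
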