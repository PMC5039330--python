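"""Stochastic individual-based generation loop.

Non-overlapping generations of fixed size N.  Each generation, parents are
sampled with replacement proportionally to their growth rate; each sampled
parent attempts one reproduction: the offspring growth rate mutates, its
damage is projected from the inherited load, and the offspring survives with
probability 1 - V(D').  Nonviable offspring are counted as selective deaths
and the slot is re-sampled, until N viable offspring have been collected.

The workhorse :func:`advance_generation` is vectorised (batches of
reproduction attempts drawn at once); the scalar operations
:func:`sample_parent`, :func:`mutate_growth` and :func:`attempt_reproduction`
expose the per-individual semantics for inspection and testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .model import ModelParams, equilibrium_damage, mortality_probability, projected_damage, repair_rate

__all__ = [
    "Cell",
    "Population",
    "ExtinctionError",
    "DegeneratePopulationError",
    "sample_parent",
    "mutate_growth",
    "attempt_reproduction",
    "advance_generation",
    "initialize_ancestral_population",
    "run_generations",
    "TRAJECTORY_COLUMNS",
]

TRAJECTORY_COLUMNS = (
    "generation",
    "mean_g",
    "var_g",
    "mean_D",
    "var_D",
    "selective_deaths",
)


class ExtinctionError(RuntimeError):
    """The attempt cap was exceeded before the next generation filled.

    Signals the regime in which offspring mortality is so pervasive that
    the population would, in effect, go extinct.
    """

    def __init__(self, generation: int, message: str | None = None):
        self.generation = generation
        super().__init__(message or f"population effectively extinct at generation {generation}")


class DegeneratePopulationError(RuntimeError):
    """All growth rates are zero: no cell can reproduce."""


class Cell(NamedTuple):
    """One individual: heritable growth rate and current damage load."""

    g: float
    D: float


@dataclass
class Population:
    """Fixed-size collection of cells plus bookkeeping counters.

    ``g`` and ``D`` are parallel arrays of length N.  ``selective_deaths``
    counts nonviable offspring produced since initialisation (or since the
    last reset) and is non-decreasing.
    """

    g: np.ndarray
    D: np.ndarray
    generation: int = 0
    selective_deaths: int = 0

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.g.shape != self.D.shape or self.g.ndim != 1 or self.g.size == 0:
            raise ValueError("g and D must be equal-length non-empty 1-D arrays")
        if np.any(self.g < 0) or np.any(self.D < 0):
            raise ValueError("growth rates and damage loads must be >= 0")

    @property
    def size(self) -> int:
        return self.g.size

    def cells(self) -> list[Cell]:
        return [Cell(float(a), float(b)) for a, b in zip(self.g, self.D)]

    def summary(self) -> dict[str, float]:
        return {
            "generation": self.generation,
            "mean_g": float(self.g.mean()),
            "var_g": float(self.g.var()),
            "mean_D": float(self.D.mean()),
            "var_D": float(self.D.var()),
            "selective_deaths": self.selective_deaths,
        }


def _weights(g: np.ndarray) -> np.ndarray:
    total = g.sum()
    if total <= 0:
        raise DegeneratePopulationError("all growth rates are zero; population cannot reproduce")
    return g / total


def sample_parent(pop: Population, rng: np.random.Generator) -> int:
    """Index of one parent, drawn with probability proportional to growth."""
    return int(rng.choice(pop.size, p=_weights(pop.g)))


def mutate_growth(g, p: ModelParams, rng: np.random.Generator):
    """Offspring growth rate: parental value perturbed by mutation, clamped
    to [0, g_max].

    ``gaussian`` mode perturbs every offspring by N(0, mutation_scale^2);
    ``jump`` mode moves a fraction ``mutation_rate`` of offspring by a fixed
    step of size ``mutation_scale`` (sign equiprobable).
    """
    g = np.asarray(g, dtype=float)
    if p.mutation_mode == "gaussian":
        if p.mutation_scale > 0:
            g = g + rng.normal(0.0, p.mutation_scale, size=g.shape)
    else:  # jump
        hits = rng.random(size=g.shape) < p.mutation_rate
        signs = rng.choice([-1.0, 1.0], size=g.shape)
        g = g + hits * signs * p.mutation_scale
    return np.clip(g, 0.0, p.g_max)[()]


def attempt_reproduction(parent: Cell, p: ModelParams, rng: np.random.Generator) -> Cell | None:
    """One reproduction attempt: returns the viable offspring, or None if
    the offspring was nonviable (a selective death).

    The offspring's own damage D' (inherited load relaxed toward its own
    equilibrium) determines viability, so that ``delta_t`` modulates how
    strongly an offspring's growth choice feeds back on its survival.
    """
    g_off = float(mutate_growth(parent.g, p, rng))
    d_off = float(projected_damage(parent.D, g_off, p))
    if rng.random() < float(mortality_probability(d_off, p)):
        return None
    return Cell(g_off, d_off)


def advance_generation(
    pop: Population,
    p: ModelParams,
    rng: np.random.Generator,
    max_attempt_factor: int = 1000,
) -> Population:
    """Produce the next generation (same size N), counting selective deaths.

    Reproduction attempts are drawn in vectorised batches; each batch
    samples parents growth-weighted with replacement, mutates, projects
    damage and applies viability selection.  Raises :class:`ExtinctionError`
    if more than ``max_attempt_factor * N`` attempts fail to fill the
    population.
    """
    n = pop.size
    w = _weights(pop.g)
    new_g = np.empty(n)
    new_D = np.empty(n)
    filled = 0
    attempts = 0
    deaths = 0
    cap = max_attempt_factor * n
    survival_guess = 1.0
    while filled < n:
        # Overshoot by the observed survival rate; the batch is truncated at
        # the attempt that fills the last slot, so the attempt sequence is
        # distributed exactly as one-at-a-time sampling with replacement.
        needed = n - filled
        batch = min(int(needed / max(survival_guess, 1e-3)) + 8, cap - attempts)
        if batch <= 0:
            raise ExtinctionError(pop.generation + 1)
        idx = rng.choice(n, size=batch, p=w)
        g_off = mutate_growth(pop.g[idx], p, rng)
        d_off = projected_damage(pop.D[idx], g_off, p)
        v = mortality_probability(d_off, p)
        alive = rng.random(batch) >= v
        filled_cum = np.cumsum(alive)
        if filled_cum[-1] >= needed:
            # Truncate after the attempt that produced the needed-th survivor.
            last = int(np.searchsorted(filled_cum, needed)) + 1
            alive = alive[:last]
            g_off, d_off = g_off[:last], d_off[:last]
            k = needed
        else:
            last = batch
            k = int(filled_cum[-1])
        deaths += last - k
        attempts += last
        survival_guess = max(k / last, 1e-3) if last else 1e-3
        keep = alive.nonzero()[0]
        new_g[filled : filled + k] = g_off[keep]
        new_D[filled : filled + k] = d_off[keep]
        filled += k
        if filled < n and attempts >= cap:
            raise ExtinctionError(pop.generation + 1)
    return Population(
        g=new_g,
        D=new_D,
        generation=pop.generation + 1,
        selective_deaths=pop.selective_deaths + deaths,
    )


def initialize_ancestral_population(
    p_ancestral: ModelParams,
    N: int,
    burn_in: int = 1000,
    rng: np.random.Generator | None = None,
    g_init: float = 0.5,
    max_attempt_factor: int = 1000,
) -> Population:
    """Seed N identical cells at ``g_init`` with equilibrium damage, then
    equilibrate for ``burn_in`` generations under the ancestral environment.

    The selective-death counter is reset to zero afterwards, so deaths
    reported by subsequent evolution exclude the equilibration phase.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if rng is None:
        rng = np.random.default_rng()
    d0 = float(equilibrium_damage(g_init, p_ancestral))
    pop = Population(g=np.full(N, float(g_init)), D=np.full(N, d0))
    for _ in range(burn_in):
        pop = advance_generation(pop, p_ancestral, rng, max_attempt_factor)
    pop.selective_deaths = 0
    pop.generation = 0
    return pop


def run_generations(
    pop: Population,
    p: ModelParams,
    generations: int,
    rng: np.random.Generator,
    record_every: int = 0,
    max_attempt_factor: int = 1000,
) -> tuple[Population, pd.DataFrame]:
    """Evolve ``pop`` for ``generations`` generations under parameters ``p``.

    Returns the final population and a trajectory table.  With
    ``record_every = k > 0`` the trajectory holds every k-th generation
    (always including the first and last); with 0 only the initial and
    final states are recorded.
    """
    rows = [pop.summary()]
    for i in range(generations):
        pop = advance_generation(pop, p, rng, max_attempt_factor)
        if (record_every and pop.generation % record_every == 0) or i == generations - 1:
            rows.append(pop.summary())
    traj = pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS)).drop_duplicates("generation")
    return pop, traj.reset_index(drop=True)
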