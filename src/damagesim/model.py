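"""Deterministic core of the growth–damage–repair life-history model.

A cell divides at a heritable rate ``g`` and carries a dimensionless damage
load ``D`` (oxidised components, misfolded proteins, ...).  Damage accrues in
proportion to growth and is removed by repair, which trades off linearly
against growth because resources allocated to division cannot fuel repair
machinery:

    dD/dt   = g * D_max - R(g) * D
    R(g)    = R_max - s * (R_max - R_min) * g / g_span      (clamped)
    D_eq(g) = g * D_max / R(g)

A daughter cell inherits its parent's damage and relaxes toward its own
equilibrium over a relaxation time ``delta_t``:

    D' = D_eq(g) + (D_p - D_eq(g)) * exp(-R(g) * delta_t)

``delta_t = 0`` means damage is entirely parental; large ``delta_t`` means
damage is entirely determined by the daughter's own growth rate.  Damage
kills: the probability that a daughter is nonviable is a Hill function

    V(D) = D^alpha / (K^alpha + D^alpha)

with half-maximal mortality at ``D = K`` and steepness ``alpha``.

Everything in this module is pure and deterministic; all functions accept
scalars or numpy arrays of growth/damage values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ModelParams",
    "repair_rate",
    "damage_derivative",
    "equilibrium_damage",
    "projected_damage",
    "mortality_probability",
    "viable_equilibrium_growth",
    "predicted_equilibrium_growth",
]


@dataclass(frozen=True)
class ModelParams:
    """All parameters of one environment.

    Parameters
    ----------
    g_max:
        Maximum permitted growth rate in this environment (1.0 ancestral,
        2.0 enriched).  Offspring growth rates are clamped to [0, g_max].
    D_max:
        Maximum rate of damage accrual per unit growth.
    R_max:
        Repair rate when all resources are devoted to repair.
    R_min:
        Minimum repair rate; must be strictly positive so equilibrium damage
        stays finite at maximal growth.
    repair_slope:
        Slope ``s`` of the repair–growth trade-off in (0, 1]; 1 in the
        reference physiology, 0.25 for cheap repair.
    K:
        Damage level at which the mortality probability is 0.5.  If omitted,
        defaults to half the equilibrium damage at maximal growth over the
        repair span, ``D_eq(g_span) / 2`` — the reference-scenario anchoring.
    alpha:
        Hill steepness of the damage–mortality relationship.
    delta_t:
        Relaxation time weighting offspring vs parental control of damage.
    mutation_scale:
        Standard deviation of the Gaussian mutation applied to offspring
        growth (``"gaussian"`` mode), or the fixed effect size in
        ``"jump"`` mode.
    mutation_mode:
        ``"gaussian"``: every offspring receives a zero-mean Gaussian
        perturbation of s.d. ``mutation_scale``.  ``"jump"``: with
        probability ``mutation_rate`` the offspring growth moves by
        ``±mutation_scale`` (sign equiprobable).
    mutation_rate:
        Per-offspring mutation probability, used only in ``"jump"`` mode.
    inheritance_factor:
        Fraction of parental damage present in the daughter immediately
        after division (1.0 by default; 0.5 models symmetric dilution).
    g_span:
        Growth rate at which the repair trade-off bottoms out at ``R_min``.
        Defaults to ``g_max``.  Enriched environments that keep the
        ancestral repair physiology retain the ancestral span (1.0) even
        though ``g_max`` is raised to 2.0, so that growing beyond the
        ancestrally attainable range cannot buy extra repair.
    """

    g_max: float = 1.0
    D_max: float = 5.0
    R_max: float = 5.0
    R_min: float = 0.1
    repair_slope: float = 1.0
    K: float | None = None
    alpha: float = 4.0
    delta_t: float = 0.1
    mutation_scale: float = 0.05
    mutation_mode: str = "jump"
    mutation_rate: float = 0.05
    inheritance_factor: float = 1.0
    g_span: float | None = None

    def __post_init__(self) -> None:
        if self.g_span is None:
            object.__setattr__(self, "g_span", float(self.g_max))
        for name in ("g_max", "D_max", "R_max", "R_min", "g_span"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not 0 < self.repair_slope <= 1:
            raise ValueError(f"repair_slope must be in (0, 1], got {self.repair_slope!r}")
        if self.R_min > self.R_max:
            raise ValueError("R_min must not exceed R_max")
        if self.delta_t < 0:
            raise ValueError("delta_t must be >= 0")
        if self.mutation_scale < 0:
            raise ValueError("mutation_scale must be >= 0")
        if self.mutation_mode not in ("gaussian", "jump"):
            raise ValueError(f"unknown mutation_mode {self.mutation_mode!r}")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0 <= self.inheritance_factor <= 1:
            raise ValueError("inheritance_factor must be in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.K is None:
            # Reference anchoring: half-mortality at half the maximal
            # equilibrium damage of this physiology.
            object.__setattr__(
                self, "K", float(equilibrium_damage(self.g_span, self, _validate=False)) / 2.0
            )
        if not np.isfinite(self.K) or self.K <= 0:
            raise ValueError(f"K must be finite and > 0, got {self.K!r}")

    def with_(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def _check_growth(g: np.ndarray | float, p: ModelParams) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if np.any(g < 0) or np.any(g > p.g_max):
        raise ValueError(f"growth rate outside [0, {p.g_max}]")
    return g


def repair_rate(g, p: ModelParams, _validate: bool = True):
    """Repair rate R(g): linear trade-off against growth, clamped to
    [R_min, R_max].

    The decrement spans the repair physiology's range ``g_span``:
    ``R = R_max - repair_slope * (R_max - R_min) * g / g_span``.
    With ``repair_slope = 1`` and ``g_span = 1`` this reduces to the plain
    linear trade-off R_max*(1-g) + R_min*g.
    """
    if _validate:
        g = _check_growth(g, p)
    else:
        g = np.asarray(g, dtype=float)
    r = p.R_max - p.repair_slope * (p.R_max - p.R_min) * g / p.g_span
    return np.clip(r, p.R_min, p.R_max)[()]


def damage_derivative(D, g, p: ModelParams):
    """Instantaneous rate of damage change dD/dt = g*D_max - R(g)*D."""
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("damage must be >= 0")
    g = _check_growth(g, p)
    return (g * p.D_max - repair_rate(g, p) * D)[()]


def equilibrium_damage(g, p: ModelParams, _validate: bool = True):
    """Steady-state damage D_eq(g) = g * D_max / R(g) for a cell growing at g."""
    if _validate:
        g = _check_growth(g, p)
    else:
        g = np.asarray(g, dtype=float)
    return (g * p.D_max / repair_rate(g, p, _validate=False))[()]


def projected_damage(D_p, g, p: ModelParams):
    """Offspring damage after relaxing inherited damage toward its own
    equilibrium for a time ``delta_t``:

    ``D' = D_eq(g) + (f*D_p - D_eq(g)) * exp(-R(g) * delta_t)``

    where ``f`` is the parental inheritance factor (1 by default).  The
    result always lies between the inherited load and ``D_eq(g)``.
    """
    D_p = np.asarray(D_p, dtype=float)
    if np.any(D_p < 0):
        raise ValueError("parental damage must be >= 0")
    g = _check_growth(g, p)
    d_eq = equilibrium_damage(g, p, _validate=False)
    d0 = p.inheritance_factor * D_p
    return (d_eq + (d0 - d_eq) * np.exp(-repair_rate(g, p, _validate=False) * p.delta_t))[()]


def mortality_probability(D, p: ModelParams):
    """Probability V(D) that a daughter with damage D is nonviable.

    Hill function ``D^alpha / (K^alpha + D^alpha)``; V(0) = 0, V(K) = 0.5,
    saturating below 1.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("damage must be >= 0")
    # 1 / (1 + (K/D)^alpha) never overflows for large D (unlike D^alpha).
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(D > 0, p.K / np.where(D > 0, D, 1.0), np.inf)
        return (1.0 / (1.0 + ratio**p.alpha))[()]


def viable_equilibrium_growth(g, p: ModelParams):
    """Expected viable-offspring production rate (1 - V(D_eq(g))) * g.

    This is the effective growth of a lineage whose damage is entirely
    determined by its own growth (the large-``delta_t`` limit).
    """
    g = _check_growth(g, p)
    return ((1.0 - mortality_probability(equilibrium_damage(g, p, _validate=False), p)) * g)[()]


def predicted_equilibrium_growth(p: ModelParams, grid_size: int = 4096) -> tuple[float, float]:
    """Argmax and max of :func:`viable_equilibrium_growth` over [0, g_max].

    This is the deterministic prediction for the evolved growth rate when
    damage depends entirely on offspring growth (the horizontal reference
    line of the result figures).  A coarse grid locates the basin; bounded
    scalar optimisation refines it.

    Returns
    -------
    (g_star, w_star):
        The optimal growth rate and the effective growth achieved there.
    """
    grid = np.linspace(0.0, p.g_max, grid_size)
    values = viable_equilibrium_growth(grid, p)
    i = int(np.argmax(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    if hi <= lo:
        return float(grid[i]), float(values[i])
    res = minimize_scalar(
        lambda g: -viable_equilibrium_growth(g, p),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    g_star = float(res.x)
    w_star = float(viable_equilibrium_growth(g_star, p))
    # Keep the grid point if the refinement somehow did worse.
    if values[i] > w_star:
        return float(grid[i]), float(values[i])
    return g_star, w_star
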