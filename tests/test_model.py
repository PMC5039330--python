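"""Deterministic model functions against closed forms and an ODE oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from damagesim import (
    ModelParams,
    damage_derivative,
    equilibrium_damage,
    mortality_probability,
    predicted_equilibrium_growth,
    projected_damage,
    repair_rate,
    viable_equilibrium_growth,
)


def integrate_damage(D0: float, g: float, p: ModelParams, duration: float) -> float:
    """Independent oracle: numerically integrate dD/dt = g*D_max - R*D."""
    r = float(repair_rate(g, p))
    sol = solve_ivp(
        lambda t, y: g * p.D_max - r * y,
        (0.0, duration),
        [D0],
        rtol=1e-11,
        atol=1e-12,
    )
    return float(sol.y[0, -1])


class TestRepairRate:
    def test_no_growth_gives_maximal_repair(self, params):
        assert repair_rate(0.0, params) == params.R_max

    def test_full_growth_gives_minimal_repair(self, params):
        assert repair_rate(params.g_max, params) == pytest.approx(params.R_min)

    def test_shallow_slope_arithmetic(self):
        p = ModelParams(R_max=5.0, R_min=1.0, repair_slope=0.25)
        assert repair_rate(0.5 * p.g_max, p) == pytest.approx(5 - 0.25 * 4 * 0.5)

    def test_rejects_growth_outside_range(self, params):
        with pytest.raises(ValueError):
            repair_rate(-0.1, params)
        with pytest.raises(ValueError):
            repair_rate(params.g_max + 0.1, params)

    @given(
        g=st.floats(0.0, 2.0),
        slope=st.floats(0.01, 1.0),
        r_min=st.floats(0.001, 5.0),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_bounded_and_nonincreasing(self, g, slope, r_min):
        p = ModelParams(g_max=2.0, R_min=r_min, repair_slope=slope)
        r = repair_rate(g, p)
        assert p.R_min <= r <= p.R_max
        grid = np.linspace(0, p.g_max, 101)
        values = repair_rate(grid, p)
        assert np.all(np.diff(values) <= 1e-12)


class TestDamageDerivative:
    def test_zero_at_equilibrium(self, params):
        for g in (0.1, 0.5, 0.9):
            d_eq = equilibrium_damage(g, params)
            assert damage_derivative(d_eq, g, params) == pytest.approx(0.0, abs=1e-12)

    def test_pure_decay_without_growth(self):
        p = ModelParams(R_max=5.0, repair_slope=1.0)
        assert damage_derivative(1.0, 0.0, p) == pytest.approx(-5.0)

    def test_undamaged_cells_accrue_at_growth_rate(self, params):
        assert damage_derivative(0.0, 0.4, params) == pytest.approx(0.4 * params.D_max)

    def test_rejects_negative_damage(self, params):
        with pytest.raises(ValueError):
            damage_derivative(-1.0, 0.5, params)


class TestEquilibriumDamage:
    def test_zero_growth_zero_damage(self, params):
        assert equilibrium_damage(0.0, params) == 0.0

    def test_closed_form_at_full_growth(self):
        p = ModelParams(g_max=1.0, D_max=5.0, R_max=5.0, R_min=1.0)
        assert equilibrium_damage(1.0, p) == pytest.approx(5.0)

    def test_matches_ode_fixed_point(self):
        """For random (g, params) the ODE relaxes to D_eq (1e-8)."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = ModelParams(
                g_max=rng.choice([1.0, 2.0]),
                D_max=rng.uniform(1, 8),
                R_max=rng.uniform(2, 8),
                R_min=rng.uniform(0.05, 1.5),
                repair_slope=rng.uniform(0.1, 1.0),
            )
            g = rng.uniform(0, p.g_max)
            d_eq = float(equilibrium_damage(g, p))
            # Integrate long enough for full relaxation at rate R >= R_min.
            horizon = 40.0 / float(repair_rate(g, p))
            assert integrate_damage(d_eq + 1.0, g, p, horizon) == pytest.approx(d_eq, abs=1e-8)

    def test_strictly_increasing_in_growth(self, params):
        grid = np.linspace(0, params.g_max, 400)
        values = equilibrium_damage(grid, params)
        assert np.all(np.diff(values) > 0)


class TestProjectedDamage:
    def test_zero_relaxation_keeps_parental_damage(self):
        p = ModelParams(delta_t=0.0)
        assert projected_damage(3.7, 0.6, p) == 3.7

    def test_infinite_relaxation_reaches_own_equilibrium(self):
        p = ModelParams(delta_t=1e6)
        assert projected_damage(3.7, 0.6, p) == pytest.approx(equilibrium_damage(0.6, p))

    def test_closed_form_value(self):
        # D_p=2 relaxing toward D_eq=5 at R=1 over 0.1 time units.
        p = ModelParams(g_max=1.0, D_max=5.0, R_max=5.0, R_min=1.0, delta_t=0.1)
        expected = 5 + (2 - 5) * np.exp(-0.1)
        assert projected_damage(2.0, 1.0, p) == pytest.approx(expected)
        assert expected == pytest.approx(2.2855, abs=5e-4)

    def test_matches_ode_integration(self):
        """The closed form equals integrating the damage ODE for delta_t."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            p = ModelParams(
                g_max=2.0,
                R_min=rng.uniform(0.05, 1.0),
                delta_t=rng.uniform(0.01, 2.0),
            )
            g = rng.uniform(0, p.g_max)
            d_p = rng.uniform(0, 20)
            oracle = integrate_damage(d_p, g, p, p.delta_t)
            assert projected_damage(d_p, g, p) == pytest.approx(oracle, abs=1e-8)

    @given(d_p=st.floats(0, 50), g=st.floats(0, 1), dt=st.floats(0, 100))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_interpolates_between_parent_and_equilibrium(self, d_p, g, dt):
        p = ModelParams(delta_t=dt)
        d = projected_damage(d_p, g, p)
        d_eq = equilibrium_damage(g, p)
        lo, hi = min(d_p, d_eq), max(d_p, d_eq)
        assert lo - 1e-9 <= d <= hi + 1e-9

    def test_monotone_in_delta_t_toward_equilibrium(self):
        g, d_p = 0.5, 10.0
        d_eq = float(equilibrium_damage(g, ModelParams()))
        values = [float(projected_damage(d_p, g, ModelParams(delta_t=dt))) for dt in np.linspace(0, 5, 50)]
        assert np.all(np.diff(values) < 0)  # decreasing toward D_eq < D_p
        assert values[-1] > d_eq

    def test_rejects_negative_parental_damage(self, params):
        with pytest.raises(ValueError):
            projected_damage(-0.5, 0.5, params)


class TestMortalityProbability:
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0, 4.0, 10.0])
    def test_half_mortality_at_tolerance_threshold(self, alpha):
        p = ModelParams(alpha=alpha)
        assert mortality_probability(p.K, p) == pytest.approx(0.5)

    def test_no_damage_no_mortality(self, params):
        assert mortality_probability(0.0, params) == 0.0

    def test_double_tolerance_quadratic_hill(self):
        p = ModelParams(alpha=2.0)
        assert mortality_probability(2 * p.K, p) == pytest.approx(0.8)

    @given(alpha=st.floats(0.2, 20), scale=st.floats(0.01, 100))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_monotone_into_unit_interval(self, alpha, scale):
        p = ModelParams(alpha=alpha)
        grid = np.linspace(0, scale * p.K, 201)
        v = mortality_probability(grid, p)
        assert np.all(v >= 0) and np.all(v <= 1)
        # Strictly below 1 wherever the Hill ratio is representable.
        assert np.all(v[grid <= 2 * p.K] < 1)
        assert np.all(np.diff(v) >= -1e-12)


class TestEquilibriumGrowthPrediction:
    def test_no_growth_no_output(self, params):
        assert viable_equilibrium_growth(0.0, params) == 0.0

    def test_half_output_where_equilibrium_damage_hits_tolerance(self, params):
        # Find g with D_eq(g) = K by bisection, check effective growth = g/2.
        from scipy.optimize import brentq

        g_k = brentq(lambda g: float(equilibrium_damage(g, params)) - params.K, 1e-9, params.g_max)
        assert viable_equilibrium_growth(g_k, params) == pytest.approx(0.5 * g_k)

    @pytest.mark.parametrize("g_max,alpha", [(1.0, 2.0), (1.0, 4.0), (2.0, 10.0)])
    def test_optimum_matches_dense_grid_search(self, g_max, alpha):
        p = ModelParams(g_max=g_max, alpha=alpha)
        grid = np.linspace(0, p.g_max, 100_000)
        values = viable_equilibrium_growth(grid, p)
        g_brute = grid[np.argmax(values)]
        g_star, w_star = predicted_equilibrium_growth(p)
        assert g_star == pytest.approx(g_brute, abs=1e-4)
        assert w_star >= values.max() - 1e-9

    def test_unbinding_mortality_pushes_optimum_to_ceiling(self):
        p = ModelParams(K=1e9)
        g_star, w_star = predicted_equilibrium_growth(p)
        assert g_star == pytest.approx(p.g_max, abs=1e-6)
        assert w_star == pytest.approx(p.g_max, rel=1e-6)

    def test_steep_hill_limits_growth_at_tolerance_boundary(self):
        from scipy.optimize import brentq

        p = ModelParams(alpha=400.0)
        g_k = brentq(lambda g: float(equilibrium_damage(g, p)) - p.K, 1e-9, p.g_max)
        g_star, _ = predicted_equilibrium_growth(p)
        assert g_star == pytest.approx(g_k, abs=5e-3)


class TestModelParams:
    def test_tolerance_anchored_at_half_max_equilibrium_damage(self):
        p = ModelParams(g_max=1.0, D_max=5.0, R_max=5.0, R_min=0.5)
        assert p.K == pytest.approx(equilibrium_damage(1.0, p) / 2)

    @pytest.mark.parametrize(
        "bad",
        [
            {"R_min": -1.0},
            {"R_min": 9.0},  # exceeds R_max
            {"repair_slope": 0.0},
            {"repair_slope": 1.5},
            {"delta_t": -0.1},
            {"alpha": 0.0},
            {"mutation_mode": "saltation"},
            {"inheritance_factor": 2.0},
        ],
    )
    def test_rejects_invalid_parameters(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)

    def test_with_replaces_fields(self, params):
        q = params.with_(alpha=10.0)
        assert q.alpha == 10.0 and q.D_max == params.D_max
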