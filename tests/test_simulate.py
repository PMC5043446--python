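"""Deterministic integration and Gillespie simulation."""

import numpy as np
import pytest

from procdesign.simulate import (
    SamplingGrid,
    SimulationError,
    simulate_ode,
    simulate_ssa,
)

from conftest import make_network


class TestSamplingGrid:
    def test_regular_40hz_grid_has_1121_points(self):
        grid = SamplingGrid.regular(0.0, 28.0, 40.0)
        assert len(grid) == 1121

    def test_integer_grid_has_101_points(self):
        grid = SamplingGrid.integers(0, 100)
        assert len(grid) == 101

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            SamplingGrid(0.0, 1.0, np.array([0.0, 0.5, 0.4, 1.0]))


class TestOde:
    def test_exponential_decay_hits_e_minus_one(self, decay_net):
        grid = SamplingGrid(0.0, 1.0, np.linspace(0, 1, 11))
        traj = simulate_ode(decay_net, {"k": 1.0}, grid)
        assert traj.get("A")[-1] == pytest.approx(np.exp(-1), rel=1e-5)

    def test_zero_rate_network_constant(self, decay_net):
        grid = SamplingGrid(0.0, 5.0, np.linspace(0, 5, 6))
        traj = simulate_ode(decay_net, {"k": 0.0}, grid)
        assert np.all(traj.get("A") == 1.0)

    def test_grid_refinement_invariance(self, binding_net):
        params = {"kf": 2.0, "kb": 0.3}
        coarse = SamplingGrid(0.0, 4.0, np.linspace(0, 4, 5))
        fine = SamplingGrid(0.0, 4.0, np.linspace(0, 4, 401))
        a = simulate_ode(binding_net, params, coarse).get("A")
        b = simulate_ode(binding_net, params, fine).get("A")[::100]
        assert np.allclose(a, b, rtol=1e-5, atol=1e-8)

    def test_rk45_agrees_with_lsoda_on_hill_system(
        self, osc_candidates, osc_lib, osc_model
    ):
        from procdesign.network import flatten

        net = flatten(osc_candidates[0], osc_lib, osc_model)
        params = {n: 0.3 * (lo + hi) for n, (lo, hi) in net.free_parameters}
        grid = SamplingGrid(0.0, 5.0, np.linspace(0, 5, 201))
        a = simulate_ode(net, params, grid, method="rk45")
        b = simulate_ode(net, params, grid, method="lsoda")
        assert a.ok and b.ok
        assert np.allclose(a.values, b.values, rtol=1e-4, atol=1e-6)

    def test_events_inject_species(self, decay_net):
        grid = SamplingGrid(0.0, 2.0, np.linspace(0, 2, 21))
        traj = simulate_ode(decay_net, {"k": 0.0}, grid, events=[(1.0, "A", 2.0)])
        assert traj.get("A")[0] == 1.0
        assert traj.get("A")[10] == 3.0  # right-continuous at the event
        assert traj.get("A")[-1] == 3.0


class TestSsa:
    def test_linear_death_matches_analytic_mean(self, decay_net):
        decay_net.initial["A"] = 100.0
        grid = SamplingGrid(0.0, 10.0, np.linspace(0, 10, 11))
        n_real = 1000
        traj = simulate_ssa(decay_net, {"k": 0.1}, grid, n_real=n_real, seed=42)
        mean_t10 = traj.get("A")[-1]
        expected = 100 * np.exp(-1.0)
        # variance of a pure-death binomial thinning at t
        p = np.exp(-1.0)
        se = np.sqrt(100 * p * (1 - p) / n_real)
        assert abs(mean_t10 - expected) < 3 * se

    def test_same_seed_bit_identical(self, birth_death_net):
        grid = SamplingGrid.integers(0, 20)
        kw = dict(params={"b": 5.0, "d": 0.5}, grid=grid, n_real=50, seed=7)
        a = simulate_ssa(birth_death_net, **kw)
        b = simulate_ssa(birth_death_net, **kw)
        assert np.array_equal(a.values, b.values)

    def test_different_seed_differs(self, birth_death_net):
        grid = SamplingGrid.integers(0, 20)
        a = simulate_ssa(birth_death_net, {"b": 5.0, "d": 0.5}, grid, n_real=50, seed=7)
        b = simulate_ssa(birth_death_net, {"b": 5.0, "d": 0.5}, grid, n_real=50, seed=8)
        assert not np.array_equal(a.values, b.values)

    def test_zero_propensity_network_constant(self, decay_net):
        decay_net.initial["A"] = 5.0
        grid = SamplingGrid.integers(0, 10)
        traj = simulate_ssa(decay_net, {"k": 0.0}, grid, n_real=10, seed=1)
        assert np.all(traj.values == 5.0)

    def test_ensemble_mean_converges_to_ode_at_sqrt_rate(self, birth_death_net):
        """Linear network: SSA ensemble mean approaches the ODE solution;
        the deviation shrinks roughly like n_real^(-1/2)."""
        grid = SamplingGrid.integers(0, 10)
        params = {"b": 5.0, "d": 0.5}
        ode = simulate_ode(birth_death_net, params, grid).get("A")
        devs = []
        for n_real in (100, 400, 1600):
            ssa = simulate_ssa(birth_death_net, params, grid, n_real=n_real, seed=3)
            devs.append(np.max(np.abs(ssa.get("A") - ode)))
        assert devs[2] < devs[0]
        # total shrinkage over a 16x ensemble growth is near the ideal 4x
        assert devs[2] < devs[0] / 1.5

    def test_state_cap_aborts_realization(self, birth_death_net):
        grid = SamplingGrid.integers(0, 10)
        with pytest.raises(SimulationError):
            simulate_ssa(
                birth_death_net, {"b": 1000.0, "d": 0.0}, grid,
                n_real=5, seed=1, max_total=50,
            )
        traj = simulate_ssa(
            birth_death_net, {"b": 1000.0, "d": 0.0}, grid,
            n_real=5, seed=1, max_total=50, on_failure="flag",
        )
        assert not traj.ok
        assert traj.n_failed == 5

    def test_events_drive_inducer_injection(self):
        net = make_network(
            ["S", "A", "SA"],
            [([("S", 1), ("A", 1)], [("SA", 1)], "k")],
            {"k": 10.0},
            initial={"A": 50.0},
        )
        grid = SamplingGrid.integers(0, 10)
        traj = simulate_ssa(net, {"k": 10.0}, grid, n_real=20, seed=5,
                            events=[(5.0, "S", 100.0)])
        a = traj.get("A")
        assert np.all(a[:5] == 50.0)  # nothing happens before the pulse
        assert a[-1] < 5.0  # sequestration wipes out free A
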