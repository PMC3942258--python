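import numpy as np
import pytest

from cdipatterns import (
    IntegrationSettings,
    ModelParams,
    PopulationState,
    integrate_for,
    integrate_to_convergence,
    integrate_with_snapshots,
)
from cdipatterns.integrate import clamp_negatives


class TestSettings:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"max_error_per_step": 0.0},
            {"max_step": -1.0},
            {"convergence_tol_factor": 0.0},
            {"convergence_window": 0},
            {"max_time": 0.0},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            IntegrationSettings(**kwargs)


class TestConvergence:
    def test_logistic_relaxes_to_carrying_capacity(self, settings):
        p = ModelParams(alpha=2.5, c=3.0, D=1e-3, n_grid=8)
        st = PopulationState(np.full(8, 0.1), np.zeros(8))
        res = integrate_to_convergence(st, p, settings)
        assert res.converged
        assert np.allclose(res.state.u, 2.5, atol=1e-6)
        assert np.all(res.state.v == 0.0)

    def test_u_always_wins_region(self, settings):
        # growth advantage 2, weak inhibition c=0.5: CDI- excludes CDI+
        p = ModelParams(alpha=2.0, beta=1.0, c=0.5)
        rng = np.random.default_rng(11)
        for _ in range(5):
            st = PopulationState(rng.uniform(0.01, 2.0), rng.uniform(0.01, 1.0))
            res = integrate_to_convergence(st, p, settings)
            assert res.converged
            assert float(res.state.u) == pytest.approx(2.0, abs=1e-5)
            assert float(res.state.v) < 1e-6

    def test_v_always_wins_region(self, settings):
        # growth advantage 0.5, strong inhibition: CDI+ excludes CDI-
        p = ModelParams(alpha=0.5, beta=1.0, c=2.0)
        rng = np.random.default_rng(12)
        for _ in range(5):
            st = PopulationState(rng.uniform(0.01, 0.5), rng.uniform(0.01, 1.0))
            res = integrate_to_convergence(st, p, settings)
            assert res.converged
            assert float(res.state.v) == pytest.approx(1.0, abs=1e-5)
            assert float(res.state.u) < 1e-6

    def test_bistable_region_winner_depends_on_initial_condition(self, settings):
        p = ModelParams(alpha=2.0, beta=1.0, c=2.0)
        res_u = integrate_to_convergence(PopulationState(2.0, 0.01), p, settings)
        assert float(res_u.state.u) == pytest.approx(2.0, abs=1e-5)
        assert float(res_u.state.v) < 1e-6
        res_v = integrate_to_convergence(PopulationState(0.01, 1.0), p, settings)
        assert float(res_v.state.v) == pytest.approx(1.0, abs=1e-5)
        assert float(res_v.state.u) < 1e-6

    def test_max_time_reported_as_unconverged(self):
        p = ModelParams(alpha=3.5, c=6.3, D=1e-3)
        st = PopulationState(np.full(32, 0.1), np.full(32, 0.9))
        res = integrate_to_convergence(
            st, p, IntegrationSettings(max_time=1.0)
        )
        assert not res.converged
        assert res.state.time == pytest.approx(1.0)


class TestEulerOracle:
    def test_four_site_system_agrees_with_fixed_step_euler(self, settings):
        """Independent explicit-Euler oracle (h = 1e-4) on a 4-site ring.

        Compared on a fixed horizon spanning the whole transient; at the
        respective convergence stops both solvers sit on the same slowly
        contracting mode at slightly different times, so the fixed-horizon
        comparison is the sharper equivalence check.
        """
        p = ModelParams(alpha=3.5, beta=1.0, c=6.0, D=1e-3, n_grid=4, delta=1.0)
        u0 = np.array([3.0, 0.2, 0.1, 2.0])
        v0 = np.array([0.1, 0.9, 1.0, 0.3])
        horizon = 12.0
        rk = integrate_for(PopulationState(u0, v0), p, horizon, settings)

        h = 1e-4
        u, v = u0.copy(), v0.copy()
        c1 = p.c1
        for _ in range(int(round(horizon / h))):
            vn = np.roll(v, 1) + v + np.roll(v, -1)
            du = u * (3.5 - u - v - c1 * vn) + 1e-3 * (np.roll(u, 1) - 2 * u + np.roll(u, -1))
            dv = v * (1.0 - u - v) + 1e-3 * (np.roll(v, 1) - 2 * v + np.roll(v, -1))
            u = np.maximum(u + h * du, 0.0)
            v = np.maximum(v + h * dv, 0.0)
        assert np.max(np.abs(rk.u - u)) < 1e-4
        assert np.max(np.abs(rk.v - v)) < 1e-4


class TestInvariants:
    def test_accepted_states_are_nonnegative(self, settings, rng):
        p = ModelParams(alpha=3.5, c=6.6, D=1e-3)
        for _ in range(5):
            st = PopulationState(rng.uniform(0, 3.5, 32), rng.uniform(0, 1, 32))
            res = integrate_to_convergence(st, p, settings)
            assert np.all(res.state.u >= 0.0) and np.all(res.state.v >= 0.0)

    def test_extinct_species_stays_extinct(self, settings, rng):
        """The dynamics are multiplicative in each species' own density."""
        p = ModelParams(alpha=3.5, c=6.6, D=1e-3)
        st = PopulationState(rng.uniform(0.1, 3.5, 32), np.zeros(32))
        res = integrate_to_convergence(st, p, settings)
        assert np.all(res.state.v == 0.0)
        st2 = PopulationState(np.zeros(32), rng.uniform(0.1, 1.0, 32))
        res2 = integrate_to_convergence(st2, p, settings)
        assert np.all(res2.state.u == 0.0)

    def test_identical_inputs_give_identical_trajectories(self, settings):
        p = ModelParams(alpha=3.5, c=6.6, D=1e-3)
        rng = np.random.default_rng(99)
        u0, v0 = rng.uniform(0, 3.5, 32), rng.uniform(0, 1, 32)
        a = integrate_to_convergence(PopulationState(u0, v0), p, settings)
        b = integrate_to_convergence(PopulationState(u0, v0), p, settings)
        assert np.array_equal(a.state.u, b.state.u)
        assert np.array_equal(a.state.v, b.state.v)
        assert a.n_steps == b.n_steps


class TestClampNegatives:
    def test_tiny_negative_snapped_to_zero(self):
        s = IntegrationSettings()
        u, v, ok = clamp_negatives(np.array([1.0, -1e-9]), np.array([0.5, 0.2]), s)
        assert ok and u[1] == 0.0 and u[0] == 1.0

    def test_large_negative_rejects_the_step(self):
        s = IntegrationSettings()
        u, v, ok = clamp_negatives(np.array([1.0, -0.01]), np.array([0.5, 0.2]), s)
        assert not ok
        assert u[1] == -0.01  # untouched: caller must retry smaller

    def test_nonnegative_proposal_unchanged(self):
        s = IntegrationSettings()
        u0 = np.array([1.0, 0.0])
        v0 = np.array([0.5, 0.2])
        u, v, ok = clamp_negatives(u0, v0, s)
        assert ok and np.array_equal(u, u0) and np.array_equal(v, v0)


class TestSnapshots:
    def test_snapshots_match_direct_integration(self, settings):
        p = ModelParams(alpha=2.0, beta=1.0, c=2.0, D=1e-3, n_grid=8)
        rng = np.random.default_rng(5)
        u0, v0 = rng.uniform(0, 2, 8), rng.uniform(0, 1, 8)
        snaps = integrate_with_snapshots(
            PopulationState(u0, v0), p, [1.0, 5.0], settings
        )
        direct = integrate_for(PopulationState(u0, v0), p, 5.0, settings)
        assert snaps[1].time == pytest.approx(5.0)
        assert np.allclose(snaps[1].u, direct.u, atol=1e-9)

    def test_past_snapshot_times_rejected(self, settings):
        p = ModelParams(alpha=2.0, n_grid=8)
        st = PopulationState(np.ones(8), np.ones(8), time=10.0)
        with pytest.raises(ValueError):
            integrate_with_snapshots(st, p, [5.0], settings)
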