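import numpy as np
import pytest

from cdipatterns import (
    ModelParams,
    PopulationState,
    classify_stability,
    integrate_with_snapshots,
    lyapunov,
    lyapunov_surface,
    rhs_well_mixed,
    steady_states,
)
from cdipatterns.wellmixed import (
    BISTABLE,
    BOUNDARY,
    U_ALWAYS_WINS,
    V_ALWAYS_WINS,
    jacobian_well_mixed,
    lyapunov_gradient,
    region_label,
)


def fd_jacobian(u, v, params, eps=1e-7):
    """Finite-difference oracle for the 2x2 Jacobian.

    Central differences, falling back to forward differences at the
    nonnegativity boundary (the model rejects negative concentrations).
    """
    J = np.zeros((2, 2))
    for j, (du_, dv_) in enumerate([(eps, 0.0), (0.0, eps)]):
        fp = rhs_well_mixed(PopulationState(u + du_, v + dv_), params)
        if u - du_ >= 0 and v - dv_ >= 0:
            fm = rhs_well_mixed(PopulationState(u - du_, v - dv_), params)
            span = 2 * eps
        else:
            fm = rhs_well_mixed(PopulationState(u, v), params)
            span = eps
        J[0, j] = (fp[0] - fm[0]) / span
        J[1, j] = (fp[1] - fm[1]) / span
    return J


class TestSteadyStates:
    def test_interior_state_from_printed_formula(self):
        st = steady_states(ModelParams(alpha=2.0, beta=1.0, c=2.0))
        interior = st[-1]
        assert interior.name == "interior"
        assert (interior.u, interior.v) == pytest.approx((0.5, 0.5))
        assert interior.feasible

    def test_interior_state_alpha_3_5(self):
        st = steady_states(ModelParams(alpha=3.5, beta=1.0, c=6.0))
        interior = st[-1]
        assert interior.u == pytest.approx(1 - 2.5 / 6)
        assert interior.v == pytest.approx(2.5 / 6)

    def test_equal_growth_rates_degenerate_interior(self):
        st = steady_states(ModelParams(alpha=1.0, beta=1.0, c=2.0))
        interior = st[-1]
        assert (interior.u, interior.v) == pytest.approx((1.0, 0.0))

    def test_interior_infeasible_when_advantage_exceeds_inhibition(self):
        # alpha/beta = 4 > 1 + c = 3: u-coordinate of the interior state < 0
        st = steady_states(ModelParams(alpha=4.0, beta=1.0, c=2.0))
        assert not st[-1].feasible

    def test_zero_inhibition_has_three_states(self):
        st = steady_states(ModelParams(alpha=2.0, beta=1.0, c=0.0))
        assert len(st) == 3
        assert {s.name for s in st} == {"origin", "u_only", "v_only"}


class TestStability:
    @pytest.mark.parametrize(
        "alpha,c,expected",
        [
            (2.0, 0.5, U_ALWAYS_WINS),
            (0.5, 2.0, V_ALWAYS_WINS),
            (2.0, 2.0, BISTABLE),
        ],
    )
    def test_region_partition(self, alpha, c, expected):
        assert region_label(ModelParams(alpha=alpha, beta=1.0, c=c)) == expected

    def test_exact_region_boundaries_reported_as_boundary(self):
        assert region_label(ModelParams(alpha=1.0, beta=1.0, c=2.0)) == BOUNDARY
        assert region_label(ModelParams(alpha=3.0, beta=1.0, c=2.0)) == BOUNDARY

    def test_single_species_eigenvalues_closed_form(self):
        """(alpha,0): {-alpha, beta-alpha}; (0,beta): {-beta, alpha-beta(1+c)}."""
        p = ModelParams(alpha=2.0, beta=1.0, c=2.0)
        rep = classify_stability(p)
        by_name = {s.name: s for s in rep.states}
        assert sorted(np.real(by_name["u_only"].eigenvalues)) == pytest.approx([-2.0, -1.0])
        assert sorted(np.real(by_name["v_only"].eigenvalues)) == pytest.approx([-1.0, -1.0])
        # finite-difference cross-check at every state
        for s in rep.states:
            if s.feasible:
                J = fd_jacobian(s.u, s.v, p)
                assert np.allclose(
                    jacobian_well_mixed(s.u, s.v, p), J, atol=1e-5
                )

    def test_bistable_region_has_two_stable_extinctions_and_a_saddle(self):
        rep = classify_stability(ModelParams(alpha=2.0, beta=1.0, c=2.0))
        by_name = {s.name: s for s in rep.states}
        assert by_name["u_only"].stability == "stable"
        assert by_name["v_only"].stability == "stable"
        ev = np.real(by_name["interior"].eigenvalues)
        assert ev.min() < 0 < ev.max()  # saddle
        assert rep.region == BISTABLE

    def test_u_always_wins_stabilities(self):
        rep = classify_stability(ModelParams(alpha=2.0, beta=1.0, c=0.5))
        by_name = {s.name: s for s in rep.states}
        assert by_name["u_only"].stability == "stable"
        assert by_name["v_only"].stability == "unstable"

    def test_stability_flip_at_region_boundaries(self):
        # stability of (0, beta) flips at alpha/beta = 1 + c
        for alpha, stable in ((2.9, True), (3.1, False)):
            rep = classify_stability(ModelParams(alpha=alpha, beta=1.0, c=2.0))
            v_only = {s.name: s for s in rep.states}["v_only"]
            assert (v_only.stability == "stable") is stable
        # stability of (alpha, 0) flips at alpha/beta = 1
        for alpha, stable in ((1.1, True), (0.9, False)):
            rep = classify_stability(ModelParams(alpha=alpha, beta=1.0, c=2.0))
            u_only = {s.name: s for s in rep.states}["u_only"]
            assert (u_only.stability == "stable") is stable


class TestLyapunov:
    def test_stationary_at_every_equilibrium_in_the_flow_sense(self):
        """u dV/du = v dV/dv = 0 at all four steady states."""
        p = ModelParams(alpha=2.0, beta=1.0, c=2.0)
        for s in steady_states(p):
            gu, gv = lyapunov_gradient(s.u, s.v, p)
            assert s.u * gu == pytest.approx(0.0, abs=1e-12)
            assert s.v * gv == pytest.approx(0.0, abs=1e-12)

    def test_free_critical_point_is_the_interior_saddle(self):
        p = ModelParams(alpha=2.0, beta=1.0, c=2.0)
        gu, gv = lyapunov_gradient(0.5, 0.5, p)
        assert (gu, gv) == pytest.approx((0.0, 0.0), abs=1e-12)
        # Hessian [[1, 1+c], [1+c, 1+c]] has negative determinant: a saddle
        H = np.array([[1.0, 1.0 + p.c], [1.0 + p.c, 1.0 + p.c]])
        assert np.linalg.det(H) < 0

    def test_boundary_minima_in_the_positive_quadrant(self):
        p = ModelParams(alpha=2.0, beta=1.0, c=2.0)
        for (u0, v0) in [(2.0, 0.0), (0.0, 1.0)]:
            base = lyapunov(u0, v0, p)
            for du_, dv_ in [(0.05, 0.0), (-0.05, 0.0), (0.0, 0.05)]:
                un, vn = u0 + du_, v0 + dv_
                if un < 0 or vn < 0:
                    continue
                assert lyapunov(un, vn, p) > base

    def test_non_increasing_along_trajectories(self, settings):
        p = ModelParams(alpha=2.0, beta=1.0, c=2.0)
        rng = np.random.default_rng(8)
        for _ in range(5):
            st = PopulationState(rng.uniform(0.05, 2.0), rng.uniform(0.05, 1.0))
            snaps = integrate_with_snapshots(st, p, np.linspace(0.5, 40, 25), settings)
            vals = [float(lyapunov(s.u, s.v, p)) for s in snaps]
            assert all(b <= a + 1e-9 for a, b in zip(vals, vals[1:]))

    def test_surface_shape_and_domain(self):
        p = ModelParams(alpha=2.0, beta=1.0, c=2.0)
        surf = lyapunov_surface(p, np.linspace(0, 2.2, 12), np.linspace(0, 1.2, 7))
        assert surf.shape == (12, 7)
        with pytest.raises(ValueError):
            lyapunov_surface(p, [-0.1, 1.0], [0.0, 1.0])
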