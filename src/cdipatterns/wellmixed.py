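"""Closed-form analysis of the well-mixed (spatially homogeneous) system.

The well-mixed dynamics

    du/dt = u (alpha - u - v (1 + c)),   dv/dt = v (beta - u - v)

have four steady states: total extinction (0, 0), the two single-species
states (alpha, 0) and (0, beta), and an interior state
(beta - (alpha - beta)/c, (alpha - beta)/c).  The two species are mutually
exclusive: the interior state, when feasible, is a saddle, so competition
always ends with one species extinct.  Which extinction states are stable
partitions the (alpha/beta, c) plane into three regions:

* ``alpha/beta > 1 + c`` — the CDI- growth advantage beats the inhibition;
  u always wins.
* ``alpha/beta < 1`` — the CDI+ species both grows faster and inhibits;
  v always wins.
* ``1 < alpha/beta < 1 + c`` — both extinction states are stable and the
  winner depends on the initial condition (bistability).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .model import ModelParams

__all__ = [
    "SteadyState",
    "StabilityReport",
    "steady_states",
    "jacobian_well_mixed",
    "classify_stability",
    "region_label",
    "lyapunov",
    "lyapunov_surface",
]

U_ALWAYS_WINS = "u_always_wins"
V_ALWAYS_WINS = "v_always_wins"
BISTABLE = "bistable"
BOUNDARY = "boundary"


@dataclass
class SteadyState:
    """One homogeneous steady state with its linearization."""

    name: str
    u: float
    v: float
    feasible: bool = True
    eigenvalues: Optional[np.ndarray] = None

    @property
    def stability(self) -> Optional[str]:
        """'stable', 'unstable' (or saddle), or 'marginal' on a boundary."""
        if self.eigenvalues is None:
            return None
        re = np.real(self.eigenvalues)
        if np.any(np.abs(re) < 1e-12):
            return "marginal"
        return "stable" if np.all(re < 0) else "unstable"


@dataclass
class StabilityReport:
    states: List[SteadyState]
    region: str


def steady_states(params: ModelParams) -> List[SteadyState]:
    """The homogeneous steady states of the well-mixed system.

    With ``c > 0`` there are four; the interior coexistence state is flagged
    infeasible when either coordinate is negative.  With ``c = 0`` the
    interior state is undefined (the model degenerates to plain competition
    with a line of marginal states when ``alpha == beta``) and only the
    three boundary states are returned.
    """
    a, b, c = params.alpha, params.beta, params.c
    out = [
        SteadyState("origin", 0.0, 0.0),
        SteadyState("u_only", a, 0.0),
        SteadyState("v_only", 0.0, b),
    ]
    if c > 0:
        ui = b - (a - b) / c
        vi = (a - b) / c
        out.append(SteadyState("interior", ui, vi, feasible=(ui >= 0 and vi >= 0)))
    return out


def jacobian_well_mixed(u: float, v: float, params: ModelParams) -> np.ndarray:
    """2x2 Jacobian of the well-mixed dynamics at (u, v)."""
    a, b, c = params.alpha, params.beta, params.c
    return np.array(
        [
            [a - 2.0 * u - (1.0 + c) * v, -(1.0 + c) * u],
            [-v, b - u - 2.0 * v],
        ]
    )


def region_label(params: ModelParams, rtol: float = 1e-12) -> str:
    """Phase-region label from the exact partition of the (alpha/beta, c) plane."""
    ratio = params.alpha / params.beta
    if np.isclose(ratio, 1.0, rtol=rtol) or np.isclose(ratio, 1.0 + params.c, rtol=rtol):
        return BOUNDARY
    if ratio > 1.0 + params.c:
        return U_ALWAYS_WINS
    if ratio < 1.0:
        return V_ALWAYS_WINS
    return BISTABLE


def classify_stability(params: ModelParams) -> StabilityReport:
    """Eigenvalues of every steady state plus the phase-region label.

    At ``(alpha, 0)`` the eigenvalues are ``-alpha`` (self-limitation) and
    ``beta - alpha`` (invasion rate of v); at ``(0, beta)`` they are
    ``-beta`` and ``alpha - beta (1 + c)`` (invasion rate of u against the
    inhibition).  The stability flips of the two single-species states at
    ``alpha/beta = 1`` and ``alpha/beta = 1 + c`` generate the region
    partition.
    """
    states = steady_states(params)
    for st in states:
        st.eigenvalues = np.linalg.eigvals(
            jacobian_well_mixed(st.u, st.v, params)
        )
    return StabilityReport(states, region_label(params))


def lyapunov(u, v, params: ModelParams):
    """Lyapunov function of the well-mixed competition, vectorized over (u, v).

    After rescaling ``x1 = u, x2 = (1+c) v`` the interaction matrix of the
    competitive Lotka-Volterra system becomes symmetric, so the classical
    construction ``V = -r.x + x.A.x / 2`` applies:

        V(u, v) = -alpha u - beta (1+c) v
                  + u^2/2 + (1+c) u v + (1+c) v^2/2

    Along trajectories ``dV/dt = -(u f^2 + (1+c) v g^2) <= 0`` where f and g
    are the per-capita growth rates, so V never increases.  Its only free
    critical point is the interior saddle; the boundary extinction states
    are stationary in the flow sense (``u dV/du = v dV/dv = 0``) and are
    local minima of V restricted to the nonnegative quadrant when they are
    stable.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    a, b, c = params.alpha, params.beta, params.c
    return (
        -a * u
        - b * (1.0 + c) * v
        + 0.5 * u**2
        + (1.0 + c) * u * v
        + 0.5 * (1.0 + c) * v**2
    )


def lyapunov_gradient(u, v, params: ModelParams):
    """(dV/du, dV/dv) of :func:`lyapunov`, vectorized."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    a, b, c = params.alpha, params.beta, params.c
    dVdu = -a + u + (1.0 + c) * v
    dVdv = (1.0 + c) * (-b + u + v)
    return dVdu, dVdv


def lyapunov_surface(params: ModelParams, u_grid, v_grid) -> np.ndarray:
    """V evaluated on the outer product of u_grid and v_grid.

    Returns an array of shape ``(len(u_grid), len(v_grid))`` suitable for a
    contour plot of the bistable landscape (two boundary minima separated by
    the interior saddle).
    """
    uu, vv = np.meshgrid(np.asarray(u_grid, float), np.asarray(v_grid, float),
                         indexing="ij")
    if np.any(uu < 0) or np.any(vv < 0):
        raise ValueError("the Lyapunov surface is defined on u, v >= 0")
    return lyapunov(uu, vv, params)
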