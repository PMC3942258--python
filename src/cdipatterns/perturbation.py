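"""The frozen-diffusion (D = 0) coexistence state and the analytic pattern bound.

At D = 0 every site's steady state factorizes, giving 2^(2N) candidate
steady states.  The simplest patterned one has a u-domain and a v-domain at
their carrying capacities joined by two single-site transition layers:

    u_i = alpha,            v_i = 0      (u-domain interior)
    u_i = alpha - beta c1,  v_i = 0      (transition layers)
    u_i = 0,                v_i = beta   (v-domain interior)

The transition-layer value follows from the layer's own growth balance: its
inhibition sum over {i-1, i, i+1} is c1 * beta (one neighbor in the
v-domain), so alpha - u - c1 beta = 0 there.  Linear stability of this
state at D = 0 requires the layer and edge sites to be attracting, which
produces the necessary condition for patterned coexistence at small D:

    1 + c1 < alpha/beta < 1 + 2 c1

(the lower bound keeps v from regrowing on the layer, beta - u_layer < 0;
the upper bound keeps u from invading the v-domain edge, where the
inhibition sum is 2 c1 beta).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .model import ModelParams, PopulationState

__all__ = [
    "transition_value",
    "build_trial_state",
    "jacobian_1d",
    "stability_d0",
    "coexistence_condition",
    "StabilityResult",
]


def transition_value(params: ModelParams) -> float:
    """Steady u concentration on a single-site transition layer, alpha - beta*c1."""
    val = params.alpha - params.beta * params.c1
    if val <= 0:
        raise ValueError(
            "no positive transition layer: requires alpha > beta * c1 "
            f"(got alpha={params.alpha}, beta*c1={params.beta * params.c1})"
        )
    return val


def build_trial_state(
    params: ModelParams,
    n: Optional[int] = None,
    layers: Optional[Tuple[int, int]] = None,
) -> PopulationState:
    """Two-domain coexistence state that is exactly steady at D = 0.

    Parameters
    ----------
    n : int, optional
        Grid size; defaults to ``params.n_grid``.
    layers : (int, int), optional
        1-based positions of the two transition-layer sites; defaults to
        ``(n//2, n)``.  The v-domain fills the sites strictly between the
        first and second layer (cyclically); the u-domain fills the rest.

    The returned state zeroes the 1D right-hand side to machine precision
    when ``D = 0``; with the default layers, sites ``1 .. n/2 - 1`` are the
    u-domain and ``n/2 + 1 .. n - 1`` the v-domain.
    """
    n = int(n or params.n_grid)
    if n < 5:
        raise ValueError("need at least 5 sites for two domains plus layers")
    p, q = layers or (n // 2, n)
    if not (1 <= p <= n and 1 <= q <= n) or p == q:
        raise ValueError("layer positions must be distinct sites in 1..n")
    u_t = transition_value(params)
    u = np.empty(n)
    v = np.empty(n)
    p0, q0 = p - 1, q - 1  # 0-based
    i = p0
    u[p0] = u_t
    v[p0] = 0.0
    u[q0] = u_t
    v[q0] = 0.0
    i = (p0 + 1) % n
    while i != q0:  # v-domain between the layers
        u[i] = 0.0
        v[i] = params.beta
        i = (i + 1) % n
    i = (q0 + 1) % n
    while i != p0:  # u-domain on the complementary arc
        u[i] = params.alpha
        v[i] = 0.0
        i = (i + 1) % n
    if min((q0 - p0) % n, (p0 - q0) % n) < 2:
        raise ValueError("each domain needs at least one interior site")
    return PopulationState(u, v)


def jacobian_1d(state: PopulationState, params: ModelParams) -> np.ndarray:
    """Analytic 2N x 2N Jacobian of the 1D right-hand side at ``state``.

    Row/column ordering is ``[u_1..u_N, v_1..v_N]``.  Valid for any D
    (diffusion contributes the periodic tridiagonal ``D/delta^2`` stencil);
    only the nearest-neighbor inhibition kernel is supported.
    """
    if state.ndim != 1:
        raise ValueError("jacobian_1d expects a 1-d state")
    if params.kernel != "neighbors":
        raise NotImplementedError("analytic Jacobian implemented for the contact kernel")
    n = state.u.size
    u, v = state.u, state.v
    a, b, c1 = params.alpha, params.beta, params.c1
    dd2 = params.D / params.delta**2
    ip = np.roll(np.arange(n), -1)
    im = np.roll(np.arange(n), 1)
    vsum = v[ip] + v + v[im]

    J = np.zeros((2 * n, 2 * n))
    # du_i / du_j
    J[np.arange(n), np.arange(n)] = a - 2.0 * u - v - c1 * vsum - 2.0 * dd2
    J[np.arange(n), ip] += dd2
    J[np.arange(n), im] += dd2
    # du_i / dv_j
    J[np.arange(n), n + np.arange(n)] = -u * (1.0 + c1)
    J[np.arange(n), n + ip] += -c1 * u
    J[np.arange(n), n + im] += -c1 * u
    # dv_i / du_j
    J[n + np.arange(n), np.arange(n)] = -v
    # dv_i / dv_j
    J[n + np.arange(n), n + np.arange(n)] = b - u - 2.0 * v - 2.0 * dd2
    J[n + np.arange(n), n + ip] += dd2
    J[n + np.arange(n), n + im] += dd2
    return J


@dataclass
class StabilityResult:
    """Linear-stability verdict for a candidate steady state."""

    eigenvalues: np.ndarray
    max_real_part: float
    stable: bool


def stability_d0(
    state: PopulationState, params: ModelParams, tol: float = 1e-10
) -> StabilityResult:
    """Eigenvalue report of the frozen-diffusion Jacobian at ``state``.

    ``stable`` means every eigenvalue's real part is below ``-tol`` — strict
    negativity with a numerical margin.  Pass a params with ``D=0`` for the
    frozen-diffusion analysis, or a small D to probe the perturbed state.
    """
    lam = np.linalg.eigvals(jacobian_1d(state, params))
    max_re = float(np.max(np.real(lam)))
    return StabilityResult(lam, max_re, max_re < -tol)


def coexistence_condition(c1: float) -> Tuple[float, float]:
    """Open interval of growth advantages alpha/beta compatible with
    patterned coexistence at small D: ``(1 + c1, 1 + 2 c1)``."""
    if c1 <= 0:
        raise ValueError("c1 must be positive")
    return (1.0 + c1, 1.0 + 2.0 * c1)
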