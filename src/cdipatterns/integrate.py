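"""Adaptive time integration with negativity clamping and convergence detection.

The scheme is an embedded Runge-Kutta 4(5) (Dormand-Prince) with

* a cap of ``max_error_per_step`` on the per-step absolute error
  (max-norm over every concentration),
* a hard maximal step size,
* a negativity hook: a proposed step that drives any concentration below
  ``-max_error_per_step`` is rejected and retried with a smaller step;
  residual negatives within that threshold of zero are set to exactly zero
  before the next step,
* convergence detection: the run stops once the per-step maximal state
  change, averaged over the last ``convergence_window`` accepted steps,
  falls below ``convergence_tol_factor * max(alpha, beta)`` (the largest
  carrying capacity in the system).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from . import _kernels
from .model import ModelParams, PopulationState, _mode_and_cloc

__all__ = [
    "IntegrationSettings",
    "IntegrationResult",
    "IntegrationError",
    "integrate_to_convergence",
    "integrate_for",
    "integrate_with_snapshots",
    "clamp_negatives",
]


@dataclass(frozen=True)
class IntegrationSettings:
    """Solver tolerances and the convergence rule.

    ``convergence_window`` counts accepted solver steps (not fixed time
    units); with steps capped at ``max_step`` the window spans at least
    ``convergence_window * max_step`` time units near a steady state.
    """

    max_error_per_step: float = 1e-6
    max_step: float = 1e-1
    convergence_tol_factor: float = 1e-8
    convergence_window: int = 1000
    max_time: float = 1e6

    def __post_init__(self) -> None:
        if not (
            self.max_error_per_step > 0
            and self.max_step > 0
            and self.convergence_tol_factor > 0
            and self.max_time > 0
        ):
            raise ValueError("all tolerances and caps must be positive")
        if self.convergence_window < 1:
            raise ValueError("convergence_window must be >= 1")


@dataclass
class IntegrationResult:
    state: PopulationState
    converged: bool
    n_steps: int


class IntegrationError(RuntimeError):
    """Step-size underflow or non-finite values during integration."""


def clamp_negatives(
    u: np.ndarray, v: np.ndarray, settings: IntegrationSettings
) -> Tuple[np.ndarray, np.ndarray, bool]:
    """Negativity hook applied to a proposed post-step state.

    Returns ``(u, v, accepted)``.  If any concentration lies below
    ``-max_error_per_step`` the proposal is returned unchanged with
    ``accepted=False`` (the caller must retry with a smaller step).
    Otherwise negatives within the threshold of zero are set to exactly
    zero and the step is accepted.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    tol = settings.max_error_per_step
    if min(u.min(), v.min()) < -tol:
        return u, v, False
    return np.maximum(u, 0.0), np.maximum(v, 0.0), True


def _run(
    state: PopulationState,
    params: ModelParams,
    settings: IntegrationSettings,
    t_stop: float,
    check_conv: bool,
) -> Tuple[PopulationState, int, int]:
    mode, n_side, cloc = _mode_and_cloc(state, params)
    u = np.ascontiguousarray(state.u, dtype=np.float64).ravel().copy()
    v = np.ascontiguousarray(state.v, dtype=np.float64).ravel().copy()
    t, nsteps, status = _kernels.integrate(
        u,
        v,
        mode,
        n_side,
        params.alpha,
        params.beta,
        cloc,
        params.D / params.delta**2,
        1 if params.kernel == "onsite" else 0,
        settings.max_error_per_step,
        settings.max_step,
        settings.convergence_tol_factor * max(params.alpha, params.beta),
        settings.convergence_window,
        state.time,
        t_stop,
        check_conv,
    )
    if status == _kernels.STEP_UNDERFLOW:
        raise IntegrationError(
            f"step size underflow at t={t:.6g} (state min "
            f"{min(u.min(), v.min()):.3g}); tolerances may be inconsistent"
        )
    if status == _kernels.NONFINITE:
        raise IntegrationError(f"non-finite values encountered at t={t:.6g}")
    out = PopulationState(u.reshape(state.u.shape), v.reshape(state.v.shape), t)
    return out, nsteps, status


def integrate_to_convergence(
    state: PopulationState,
    params: ModelParams,
    settings: IntegrationSettings | None = None,
) -> IntegrationResult:
    """Integrate until the windowed convergence rule fires or max_time is hit.

    The returned state is elementwise nonnegative; ``converged`` is False
    when the ``max_time`` safety cap was reached first.
    """
    settings = settings or IntegrationSettings()
    out, nsteps, status = _run(
        state, params, settings, state.time + settings.max_time, True
    )
    return IntegrationResult(out, status == _kernels.CONVERGED, nsteps)


def integrate_for(
    state: PopulationState,
    params: ModelParams,
    duration: float,
    settings: IntegrationSettings | None = None,
) -> PopulationState:
    """Integrate over a fixed time span with no convergence stop."""
    settings = settings or IntegrationSettings()
    out, _, _ = _run(state, params, settings, state.time + duration, False)
    return out


def integrate_with_snapshots(
    state: PopulationState,
    params: ModelParams,
    times: Sequence[float],
    settings: IntegrationSettings | None = None,
) -> List[PopulationState]:
    """States at the requested absolute times (sorted, all >= state.time).

    Useful for space-time (kymograph) views of pattern formation and decay.
    """
    settings = settings or IntegrationSettings()
    times = sorted(float(t) for t in times)
    if times and times[0] < state.time:
        raise ValueError("snapshot times must not precede the state's time")
    snaps: List[PopulationState] = []
    current = state
    for t in times:
        if t > current.time:
            current, _, _ = _run(current, params, settings, t, False)
        snaps.append(current.copy())
    return snaps
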