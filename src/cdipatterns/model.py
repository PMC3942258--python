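"""Model parameters, population states, and time-derivative (RHS) functions.

The model describes competition between a toxin-delivering species (CDI+,
concentration ``v``) and a toxin-sensitive species (CDI-, concentration
``u``).  Both grow logistically on a shared resource; the CDI+ species
additionally suppresses the growth of CDI- cells on its own lattice site and
its nearest neighbors, reflecting the contact-dependent (cell-to-cell) nature
of toxin injection.  In nondimensional form the lattice dynamics in one
dimension are

    du_i/dt = u_i (alpha - u_i - v_i - c1 (v_{i+1} + v_i + v_{i-1}))
              + (D/delta^2) (u_{i+1} - 2 u_i + u_{i-1})
    dv_i/dt = v_i (beta - u_i - v_i)
              + (D/delta^2) (v_{i+1} - 2 v_i + v_{i-1})

with periodic boundaries, where ``c1 = c/3`` spreads the total inhibition
``c`` over the three 1D contact locations (on-site plus two neighbors).  In
2D the inhibition acts over the five von-Neumann locations with
``c2 = c/5`` and diffusion uses the 5-point Laplacian.  The spatially
homogeneous (well-mixed) limit is

    du/dt = u (alpha - u - v (1 + c)),   dv/dt = v (beta - u - v).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

from . import _kernels

__all__ = ["ModelParams", "PopulationState", "rhs_well_mixed", "rhs_1d", "rhs_2d"]

#: inhibition kernels: full nearest-neighbor contact, or an on-site control
#: (same total strength c concentrated on the focal site) used to probe the
#: role of the finite interaction range.
KERNELS = ("neighbors", "onsite")


@dataclass(frozen=True)
class ModelParams:
    """Constants of the competition model.

    Parameters
    ----------
    alpha : float
        Dimensionless growth rate (and carrying capacity) of the CDI-
        species ``u``.  ``alpha/beta`` is the growth advantage the CDI-
        species enjoys because it does not pay the metabolic cost of the
        toxin machinery.
    beta : float
        Dimensionless growth rate of the CDI+ species ``v``.  Experiments
        fix ``beta = 1`` so that ``alpha`` carries the ratio.
    c : float
        Total inhibition strength exerted by CDI+ on CDI-.  The per-site
        couplings ``c1 = c/3`` (1D) and ``c2 = c/5`` (2D) are derived views
        and can never be set inconsistently.
    D : float
        Diffusion constant, equal for both species.
    delta : float
        Grid spacing; only ``D/delta**2`` enters the dynamics.  The default
        of 1 makes stripe widths come out in grid points.
    n_grid : int
        Number of grid points (1D) or side length (2D).
    kernel : str
        ``"neighbors"`` for the contact-dependent model, ``"onsite"`` for
        the control with the whole inhibition collapsed onto the focal site.
    """

    alpha: float
    beta: float = 1.0
    c: float = 0.0
    D: float = 0.0
    delta: float = 1.0
    n_grid: int = 32
    kernel: str = "neighbors"

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("growth rates alpha, beta must be positive")
        if self.c < 0:
            raise ValueError("inhibition strength c must be >= 0")
        if self.D < 0:
            raise ValueError("diffusion constant D must be >= 0")
        if not self.delta > 0:
            raise ValueError("grid spacing delta must be positive")
        if self.n_grid < 3:
            raise ValueError("need at least 3 grid points for neighbor stencils")
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")

    @property
    def c1(self) -> float:
        """Per-location 1D inhibition: total c over 3 contact sites."""
        return self.c / 3.0

    @property
    def c2(self) -> float:
        """Per-location 2D inhibition: total c over 5 contact sites."""
        return self.c / 5.0

    @property
    def growth_advantage(self) -> float:
        return self.alpha / self.beta

    @classmethod
    def from_c1(cls, alpha: float, c1: float, **kwargs) -> "ModelParams":
        """Build parameters from the 1D per-site coupling ``c1`` (c = 3 c1)."""
        return cls(alpha=alpha, c=3.0 * c1, **kwargs)

    @classmethod
    def from_c2(cls, alpha: float, c2: float, **kwargs) -> "ModelParams":
        """Build parameters from the 2D per-site coupling ``c2`` (c = 5 c2)."""
        return cls(alpha=alpha, c=5.0 * c2, **kwargs)

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class PopulationState:
    """Concentration fields of the two species at one instant.

    ``u`` (CDI-) and ``v`` (CDI+) are nonnegative arrays of identical shape:
    scalars (0-d) for the well-mixed system, length-N vectors in 1D, or
    n-by-n matrices in 2D.  Spatial indexing is periodic in every axis.
    """

    u: np.ndarray
    v: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.u.shape != self.v.shape:
            raise ValueError(f"u and v shapes differ: {self.u.shape} vs {self.v.shape}")
        if self.u.ndim > 2:
            raise ValueError("states are 0-, 1- or 2-dimensional")
        if self.u.ndim == 2 and self.u.shape[0] != self.u.shape[1]:
            raise ValueError("2D fields must be square")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("non-finite concentrations")
        if np.any(self.u < 0) or np.any(self.v < 0):
            raise ValueError("concentrations must be nonnegative")

    @property
    def ndim(self) -> int:
        return self.u.ndim

    @property
    def n_sites(self) -> int:
        return self.u.size

    def copy(self) -> "PopulationState":
        return PopulationState(self.u.copy(), self.v.copy(), self.time)

    def to_dataframe(self):
        """Tidy snapshot: one row per site with u and v columns."""
        import pandas as pd

        if self.ndim == 0:
            return pd.DataFrame({"u": [float(self.u)], "v": [float(self.v)]})
        if self.ndim == 1:
            return pd.DataFrame(
                {"site_index": np.arange(self.u.size), "u": self.u, "v": self.v}
            )
        n = self.u.shape[0]
        rows, cols = np.divmod(np.arange(self.u.size), n)
        return pd.DataFrame(
            {"row": rows, "col": cols, "u": self.u.ravel(), "v": self.v.ravel()}
        )


def _mode_and_cloc(state: PopulationState, params: ModelParams) -> Tuple[int, int, float]:
    """Map a state's dimensionality to the kernel mode and coupling."""
    if state.ndim == 0:
        return 0, 1, params.c
    if state.ndim == 1:
        return 1, 1, params.c1
    return 2, state.u.shape[0], params.c2


def _rhs_dispatch(state: PopulationState, params: ModelParams):
    mode, n_side, cloc = _mode_and_cloc(state, params)
    u = np.ascontiguousarray(state.u, dtype=np.float64).ravel()
    v = np.ascontiguousarray(state.v, dtype=np.float64).ravel()
    du = np.empty_like(u)
    dv = np.empty_like(v)
    _kernels.rhs(
        mode,
        n_side,
        u,
        v,
        du,
        dv,
        params.alpha,
        params.beta,
        cloc,
        params.D / params.delta**2,
        1 if params.kernel == "onsite" else 0,
    )
    return du.reshape(state.u.shape), dv.reshape(state.v.shape)


def rhs_well_mixed(state: PopulationState, params: ModelParams):
    """Time derivative of the well-mixed system.

    Returns ``(du/dt, dv/dt)`` for a scalar state:
    ``du/dt = u (alpha - u - v (1+c))``, ``dv/dt = v (beta - u - v)``.
    """
    if state.ndim != 0:
        raise ValueError("rhs_well_mixed expects a scalar (0-d) state")
    du, dv = _rhs_dispatch(state, params)
    return float(du), float(dv)


def rhs_1d(state: PopulationState, params: ModelParams):
    """Time derivative of the 1D lattice model (periodic boundaries)."""
    if state.ndim != 1:
        raise ValueError("rhs_1d expects a 1-d state")
    if state.u.size != params.n_grid:
        raise ValueError(
            f"state has {state.u.size} sites but params.n_grid = {params.n_grid}"
        )
    return _rhs_dispatch(state, params)


def rhs_2d(state: PopulationState, params: ModelParams):
    """Time derivative of the 2D lattice model (periodic, von-Neumann CDI)."""
    if state.ndim != 2:
        raise ValueError("rhs_2d expects a 2-d state")
    return _rhs_dispatch(state, params)
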