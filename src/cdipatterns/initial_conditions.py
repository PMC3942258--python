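"""Initial-condition families for competition experiments.

Three families are used throughout:

* the 1D *representative* two-domain states (N-1 of them on an N-site
  ring): initial condition j places the CDI+ species v at carrying
  capacity on sites 1..j and the CDI- species u at carrying capacity on
  the rest, sweeping every possible domain split;
* per-site *random* fields, u_i ~ U(0, alpha) and v_i ~ U(0, beta)
  independently (uniform over the physically meaningful range bounded by
  each species' carrying capacity; the law is an option for sensitivity
  checks);
* 2D *nested-square* states: a centered square of one species at carrying
  capacity surrounded by a sea of the other, with interior areas from 4 to
  256 grid points on the 1024-point (32 x 32) grid.
"""

from __future__ import annotations

from typing import Iterable, List, Literal, Sequence, Tuple, Union

import numpy as np

from .model import ModelParams, PopulationState

__all__ = [
    "representative_ics_1d",
    "random_ic",
    "nested_square_ic",
    "nested_square_family",
    "child_seed",
]

SeedLike = Union[int, Sequence[int]]


def child_seed(master_seed: int, index: int) -> Tuple[int, int]:
    """Deterministic per-replicate seed derived from a master seed.

    The pair feeds :class:`numpy.random.SeedSequence`, so replicate streams
    are independent and reproducible; experiment outputs record the pair.
    """
    return (int(master_seed), int(index))


def representative_ics_1d(params: ModelParams, n: int | None = None) -> List[PopulationState]:
    """All N-1 two-domain initial conditions on the N-site ring.

    State j (1-based, j = 1..N-1) has v = beta on sites 1..j and u = alpha
    on sites j+1..N, with no overlap.  Together they sweep every possible
    initial domain split, which is the representative set used for phase
    boundary scans in place of massive random ensembles.
    """
    n = int(n or params.n_grid)
    if n < 2:
        raise ValueError("need at least 2 sites")
    out = []
    for j in range(1, n):
        u = np.full(n, params.alpha)
        v = np.zeros(n)
        u[:j] = 0.0
        v[:j] = params.beta
        out.append(PopulationState(u, v))
    return out


def random_ic(
    params: ModelParams,
    shape: Union[int, Tuple[int, int]],
    seed: SeedLike,
    law: Literal["capacity_uniform", "unit_uniform"] = "capacity_uniform",
) -> PopulationState:
    """Seeded random nonnegative fields; identical seed, identical state.

    ``capacity_uniform`` (default) draws u_i ~ U(0, alpha) and
    v_i ~ U(0, beta) per site; ``unit_uniform`` draws both from U(0, 1)
    regardless of the carrying capacities.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if law == "capacity_uniform":
        hi_u, hi_v = params.alpha, params.beta
    elif law == "unit_uniform":
        hi_u, hi_v = 1.0, 1.0
    else:
        raise ValueError(f"unknown law {law!r}")
    u = rng.uniform(0.0, hi_u, size=shape)
    v = rng.uniform(0.0, hi_v, size=shape)
    return PopulationState(u, v)


def nested_square_ic(
    params: ModelParams,
    side: int,
    interior_species: Literal["u", "v"],
    interior_size: int,
) -> PopulationState:
    """Centered square of one species inside a sea of the other (2D).

    ``interior_size`` is the square's area in grid points and must be a
    perfect square strictly smaller than ``side**2``; both species sit at
    their carrying capacities.
    """
    k = int(round(np.sqrt(interior_size)))
    if k * k != interior_size:
        raise ValueError("interior_size must be a perfect square of grid points")
    if interior_size >= side * side:
        raise ValueError("interior square must be strictly smaller than the grid")
    if interior_species not in ("u", "v"):
        raise ValueError("interior_species must be 'u' or 'v'")
    o = (side - k) // 2
    if interior_species == "u":
        u = np.zeros((side, side))
        v = np.full((side, side), params.beta)
        u[o : o + k, o : o + k] = params.alpha
        v[o : o + k, o : o + k] = 0.0
    else:
        u = np.full((side, side), params.alpha)
        v = np.zeros((side, side))
        u[o : o + k, o : o + k] = 0.0
        v[o : o + k, o : o + k] = params.beta
    return PopulationState(u, v)


def nested_square_family(
    params: ModelParams,
    side: int = 32,
    interior_species: Literal["u", "v"] = "u",
    sizes: Iterable[int] = tuple(k * k for k in range(2, 17, 2)),
) -> List[PopulationState]:
    """The nested-square IC set: interior areas 4..256 on a 32 x 32 grid."""
    return [nested_square_ic(params, side, interior_species, s) for s in sizes]
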