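"""Orchestration of the computational experiments.

Each experiment couples an initial-condition family to the integrator and
the pattern classifier and returns tidy tables:

* well-mixed trajectory ensembles (winner statistics per phase region),
* the 1D coexistence phase diagram over (alpha/beta, c1, D),
* random-IC ensembles and abundance/width sweeps (the stripe statistics),
* the diffusion-destruction demonstration (same IC, increasing D),
* the 2D nested-square scan over c2 and random-IC occupancy runs.

Replicate counts default to desk-scale values; the publication-scale counts
(1e4 random ICs, 100 2D runs) are a parameter away.  All randomness is
driven by a master seed through :func:`cdipatterns.initial_conditions.child_seed`,
so identical seeds give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .initial_conditions import (
    child_seed,
    nested_square_family,
    random_ic,
    representative_ics_1d,
)
from .integrate import IntegrationSettings, integrate_to_convergence
from .model import ModelParams, PopulationState
from .patterns import EnsembleStats, PatternRecord, classify, ensemble_stats

__all__ = [
    "DEFAULT_DELTA",
    "default_settings",
    "wellmixed_ensemble",
    "run_random_ensemble",
    "abundance_sweep",
    "scan_phase_diagram_1d",
    "coexistence_interval",
    "diffusion_destruction_demo",
    "occupancy_2d",
    "scan_2d",
]

#: grid spacing of the reference setup: a length-10 domain on 32 grid points.
#: Stripe widths in length units and the reported D values presuppose it.
DEFAULT_DELTA = 10.0 / 32.0


def default_settings(max_time: float = 3e5) -> IntegrationSettings:
    """Integration settings used by all experiments unless overridden.

    ``max_time=3e5`` is ample at the reference parameters (random-IC runs
    freeze within a few hundred time units) while still bounding runaway
    marginal cases.
    """
    return IntegrationSettings(max_time=max_time)


def wellmixed_ensemble(
    params: ModelParams,
    n_trajectories: int = 100,
    master_seed: int = 0,
    settings: Optional[IntegrationSettings] = None,
) -> pd.DataFrame:
    """Outcomes of random-IC well-mixed competitions.

    Each trajectory starts from scalar u ~ U(0, alpha), v ~ U(0, beta) and
    runs to convergence; the winner is the surviving species.  Returns one
    row per trajectory (u0, v0, winner, converged).
    """
    settings = settings or default_settings()
    rows = []
    for i in range(n_trajectories):
        seed = child_seed(master_seed, i)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        u0 = rng.uniform(0.0, params.alpha)
        v0 = rng.uniform(0.0, params.beta)
        res = integrate_to_convergence(PopulationState(u0, v0), params, settings)
        u, v = float(res.state.u), float(res.state.v)
        thr = 1e-4 * max(params.alpha, params.beta)
        winner = "u" if v < thr <= u else ("v" if u < thr <= v else "none")
        rows.append(
            {"u0": u0, "v0": v0, "winner": winner, "converged": res.converged}
        )
    return pd.DataFrame(rows)


def run_random_ensemble(
    params: ModelParams,
    n_ics: int,
    master_seed: int,
    settings: Optional[IntegrationSettings] = None,
    shape: Optional[Tuple[int, ...]] = None,
    law: str = "capacity_uniform",
) -> Tuple[List[PatternRecord], int]:
    """Integrate ``n_ics`` seeded random ICs to convergence and classify.

    Returns the records of converged runs plus the count of runs that hit
    the time cap (excluded from the records, reported separately so that
    abundance fractions are not biased by truncation).
    """
    settings = settings or default_settings()
    if shape is None:
        shape = (params.n_grid,)
    records: List[PatternRecord] = []
    unconverged = 0
    for i in range(n_ics):
        seed = child_seed(master_seed, i)
        state = random_ic(params, shape if len(shape) > 1 else shape[0], seed, law=law)
        res = integrate_to_convergence(state, params, settings)
        if not res.converged:
            unconverged += 1
            continue
        records.append(classify(res.state, params, seed=seed))
    return records, unconverged


def abundance_sweep(
    alpha_over_beta: float | Sequence[float],
    c1: float | Sequence[float],
    D: float = 1e-3,
    n_ics: int = 1000,
    master_seed: int = 0,
    n_grid: int = 32,
    delta: float = DEFAULT_DELTA,
    settings: Optional[IntegrationSettings] = None,
) -> pd.DataFrame:
    """Category abundances and width statistics along a parameter sweep.

    Exactly one of ``alpha_over_beta`` and ``c1`` may be a sequence (the
    swept axis); beta is fixed at 1.  Returns one row per (parameter point,
    category) with abundance and pooled width statistics in length units.
    """
    alphas = np.atleast_1d(np.asarray(alpha_over_beta, dtype=float))
    c1s = np.atleast_1d(np.asarray(c1, dtype=float))
    if alphas.size > 1 and c1s.size > 1:
        raise ValueError("sweep one parameter at a time")
    rows = []
    for k, (a, c) in enumerate(
        [(a, c) for a in alphas for c in c1s]
    ):
        params = ModelParams.from_c1(a, c, D=D, n_grid=n_grid, delta=delta)
        records, unconv = run_random_ensemble(
            params, n_ics, master_seed + k, settings
        )
        stats = ensemble_stats(records) if records else None
        if stats is None:
            continue
        for cat, frac in stats.abundance.items():
            rows.append(
                {
                    "alpha_over_beta": a,
                    "c1": c,
                    "D": D,
                    "category": cat,
                    "abundance": frac,
                    "width_mean": stats.width_mean.get(cat, np.nan),
                    "width_sd": stats.width_sd.get(cat, np.nan),
                    "width_n": stats.width_n.get(cat, 0),
                    "n_converged": stats.n_records,
                    "n_unconverged": unconv,
                }
            )
    return pd.DataFrame(rows)


def _coexists(record: PatternRecord) -> bool:
    return record.coexistence


def scan_phase_diagram_1d(
    alpha_over_beta: Sequence[float],
    c1_values: Sequence[float],
    D_values: Sequence[float] = (1e-4, 1e-3, 1e-2),
    n_grid: int = 32,
    delta: float = DEFAULT_DELTA,
    settings: Optional[IntegrationSettings] = None,
) -> pd.DataFrame:
    """Coexistence phase diagram from the representative two-domain ICs.

    For every (alpha/beta, c1, D) triple the N-1 representative ICs run to
    convergence; the point is ``coexistence_possible`` when at least one IC
    freezes into a state with both species alive.  Returns one row per
    triple with the supporting counts.
    """
    settings = settings or default_settings()
    rows = []
    for D in D_values:
        for a in alpha_over_beta:
            for c in c1_values:
                params = ModelParams.from_c1(
                    float(a), float(c), D=float(D), n_grid=n_grid, delta=delta
                )
                n_coex = 0
                n_unconv = 0
                for ic in representative_ics_1d(params):
                    res = integrate_to_convergence(ic, params, settings)
                    if not res.converged:
                        n_unconv += 1
                        continue
                    if _coexists(classify(res.state, params)):
                        n_coex += 1
                rows.append(
                    {
                        "alpha_over_beta": float(a),
                        "c1": float(c),
                        "D": float(D),
                        "outcome": "coexistence_possible" if n_coex else "extinction_only",
                        "n_coexisting_ics": n_coex,
                        "n_unconverged": n_unconv,
                    }
                )
    return pd.DataFrame(rows)


def coexistence_interval(
    c1: float,
    D: float,
    alpha_over_beta: Sequence[float],
    n_grid: int = 32,
    delta: float = DEFAULT_DELTA,
    settings: Optional[IntegrationSettings] = None,
) -> Optional[Tuple[float, float]]:
    """Smallest and largest growth advantage with coexistence on the scan grid."""
    table = scan_phase_diagram_1d(
        alpha_over_beta, [c1], [D], n_grid=n_grid, delta=delta, settings=settings
    )
    hits = table[table.outcome == "coexistence_possible"].alpha_over_beta
    if hits.empty:
        return None
    return float(hits.min()), float(hits.max())


def diffusion_destruction_demo(
    alpha_over_beta: float = 3.5,
    c1: float = 2.1,
    D_values: Sequence[float] = (1e-3, 1e-2, 1e-1),
    seed: int = 1,
    n_grid: int = 32,
    delta: float = DEFAULT_DELTA,
    settings: Optional[IntegrationSettings] = None,
    snapshot_times: Optional[Sequence[float]] = None,
) -> Dict[float, PatternRecord]:
    """One seeded random IC integrated at increasing diffusion constants.

    Diffusion destroys localized aggregates: the surviving u-stripe count is
    non-increasing in D, and at the largest value coexistence is lost
    entirely.  The same IC (fixed seed) is used for every D.
    """
    settings = settings or default_settings()
    out: Dict[float, PatternRecord] = {}
    for D in D_values:
        params = ModelParams.from_c1(
            alpha_over_beta, c1, D=float(D), n_grid=n_grid, delta=delta
        )
        state = random_ic(params, n_grid, child_seed(seed, 0))
        res = integrate_to_convergence(state, params, settings)
        out[float(D)] = classify(res.state, params, seed=child_seed(seed, 0))
    return out


def occupancy_2d(
    c2: float,
    n_runs: int = 20,
    master_seed: int = 0,
    alpha_over_beta: float = 3.5,
    D: float = 1e-3,
    side: int = 32,
    delta: float = DEFAULT_DELTA,
    settings: Optional[IntegrationSettings] = None,
) -> Tuple[List[PatternRecord], int]:
    """Random-IC 2D runs at one inhibition value; records carry u occupancy."""
    params = ModelParams.from_c2(
        alpha_over_beta, c2, D=D, n_grid=side, delta=delta
    )
    return run_random_ensemble(
        params, n_runs, master_seed, settings, shape=(side, side)
    )


def scan_2d(
    c2_values: Sequence[float],
    alpha_over_beta: float = 3.5,
    D: float = 1e-3,
    side: int = 32,
    delta: float = DEFAULT_DELTA,
    settings: Optional[IntegrationSettings] = None,
) -> pd.DataFrame:
    """Counts of stable 2D coexistence patterns for the nested-square families.

    For each c2 both IC families (interior u in a v-sea, interior v in a
    u-sea; interior areas 4..256 grid points) run to convergence; a pattern
    counts as stable coexistence when both species survive.  Returns one
    row per (c2, family).
    """
    settings = settings or default_settings()
    rows = []
    for c2 in c2_values:
        params = ModelParams.from_c2(
            alpha_over_beta, float(c2), D=D, n_grid=side, delta=delta
        )
        for family in ("u", "v"):
            n_coex = 0
            n_unconv = 0
            for ic in nested_square_family(params, side, family):
                res = integrate_to_convergence(ic, params, settings)
                if not res.converged:
                    n_unconv += 1
                    continue
                if _coexists(classify(res.state, params)):
                    n_coex += 1
            rows.append(
                {
                    "c2": float(c2),
                    "interior_species": family,
                    "n_stable_patterns": n_coex,
                    "n_unconverged": n_unconv,
                }
            )
    return pd.DataFrame(rows)
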