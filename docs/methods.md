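# Methods

## Model and nondimensional conventions

The package simulates a two-species competition in nondimensional form.
`u` is the CDI− (toxin-sensitive) species with growth rate and carrying
capacity `α`; `v` is the CDI+ (toxin-delivering) species with growth rate
`β` (fixed to 1 in all experiments, so `α` equals the growth advantage
`α/β`).  Contact-dependent inhibition acts only on `u` and only over the
nearest-neighbor contact range: three locations in 1D (`c₁ = c/3`), five in
2D (`c₂ = c/5`), where `c` is the total inhibition strength.  Both species
share one diffusion constant `D`.  Boundary conditions are periodic in
every dimension (assumed in 2D by analogy with the 1D convention; a
non-periodic variant is deliberately not offered, since nothing validates
it).

**Grid spacing.**  Only `D/δ²` enters the dynamics.  The reference setup
discretizes a domain of nondimensional length 10 with 32 grid points, so
`δ = 10/32 = 0.3125` (`experiments.DEFAULT_DELTA`); the quoted values of
`D` (1e-4 … 1e-1) presuppose this spacing, and stripe widths are reported
in length units, i.e. grid points × δ.  This calibration is forced by the
published width tables: with δ = 1 the same dynamics yield single-stripe
widths near 28 grid points, while grid × 0.3125 reproduces every tabulated
width and standard deviation to within sampling error.  `ModelParams`
keeps `delta` an explicit field, so other conventions remain available.

## Time integration

An embedded Dormand–Prince 4(5) pair with proportional step control.  The
tableau choice is an implementation detail (only "order 4–5 adaptive" is
part of the method); it is validated against a fixed-step explicit-Euler
oracle and against scipy's DOP853 to ~1e-12 on reference trajectories.

* **Error control:** per-step absolute error, max-norm over all
  concentrations, kept below `max_error_per_step` (default 1e-6); hard step
  cap `max_step = 0.1`; steps shrink by `0.9 (tol/err)^{1/5}`, bounded to
  [0.1, 5].
* **Negativity handling:** a proposed step sending any concentration below
  −1e-6 is rejected and retried smaller; surviving negatives within 1e-6 of
  zero are snapped to exactly 0 before the next step.  Extinction is
  therefore absorbing, as it should be for multiplicative dynamics.
* **Convergence rule:** the run stops when the per-step maximal state
  change, averaged over the last 1000 *accepted solver steps*, falls below
  1e-8 × max(α, β).  "Steps" is read as accepted solver steps rather than
  fixed time units; near a steady state steps sit at the 0.1 cap, so the
  window spans ≥ 100 time units either way, and ensembles tested with a
  10× longer window give identical statistics (the converged states are
  frozen to machine-level drift).
* **Safety cap:** `max_time` defaults to 1e6; the experiments layer uses
  3e5.  Random-IC runs at the reference parameters converge around
  t ≈ 100–300, so the cap is far from binding; runs that do hit it are
  reported separately and excluded from ensemble statistics rather than
  silently truncated.

The inner loop is numba-compiled (`_kernels.py`); a 32-site 1D run to
convergence costs ~2–3 ms, a 32×32 2D run ~0.1–0.4 s.

## Well-mixed analysis

Steady states and the 2×2 Jacobian are closed-form.  The region partition
(u always wins / v always wins / bistable) follows from the stability flips
of `(α, 0)` at α/β = 1 and of `(0, β)` at α/β = 1 + c; exact boundary
cases are labeled `boundary` and excluded from region statistics.  For the
bistable landscape, rescaling `x₂ = (1+c) v` makes the competition matrix
symmetric, so the classical quadratic Lyapunov function
`V = −r·x + ½ xᵀAx` applies, with
`dV/dt = −(u f² + (1+c) v g²) ≤ 0`.  Its free critical point is the
interior saddle; the extinction states are stationary in the flow sense
(`u ∂V/∂u = v ∂V/∂v = 0`) and are minima of V restricted to the
nonnegative quadrant.  Only these structural properties are asserted —
the absolute values of the published landscape are not reproduced, as its
exact normalization is not specified.

## Frozen-diffusion (D = 0) construction

At D = 0 each site's steady condition factorizes, giving 2^(2N) candidate
steady states.  The simplest patterned one — two domains at carrying
capacity joined by two single-site transition layers — is steady exactly
when the layer concentration balances its own growth:
`u_layer = α − βc₁` (the layer's inhibition sum over {i−1, i, i+1} is
c₁β).  Linear stability of the full 2N×2N Jacobian then requires
`β − u_layer < 0` (no v regrowth on the layer, α/β > 1 + c₁) and
`α − β − 2c₁β < 0` (no u invasion at the v-domain edge, α/β < 1 + 2c₁),
reproducing the analytic coexistence interval `(1 + c₁, 1 + 2c₁)`.  The
stability verdict uses strict negativity of the maximal real part with a
1e-10 margin.  Higher-order corrections in D are not constructed; small-D
behavior is probed numerically instead (the D = 1e-4 coexistence interval
at c₁ = 2 is (3.1, 4.8) on a 0.1-step scan, inside the analytic bound).

## Initial conditions and ensembles

* **Representative 1D set:** all N−1 two-domain splits (v at capacity on
  sites 1..j, u on the rest).  Used for phase-boundary scans.
* **Random fields:** per-site independent `u_i ~ U(0, α)`,
  `v_i ~ U(0, β)` — uniform over the physically meaningful range bounded
  by each carrying capacity.  The published description does not fix this
  law; the capacity-uniform choice reproduces the published 1D abundance
  and width statistics essentially exactly, which is strong evidence it is
  the right one.  A `unit_uniform` alternative is exposed for sensitivity
  checks (it badly breaks the 1D statistics).
* **Nested squares (2D):** a centered square (area 4–256 grid points) of
  one species at capacity in a sea of the other, both orientations.
* **Seeding:** a master seed plus replicate index feed
  `numpy.random.SeedSequence`, so every ensemble is bitwise reproducible
  and every record carries its seed pair.

## Pattern classification

A species is extinct when its maximum concentration is below
1e-4 × max(α, β) — far above the 1e-8-scale convergence tolerance, far
below any patterned amplitude.  Coexistence states are labeled per site by
dominance (`u > v`); label runs under periodic wraparound give stripe
widths, and the number of u-domains defines single/double/multi-stripe.
Transition-layer sites (u > 0, v = 0) label as u, so a u-stripe includes
its two buffer sites.  Width tables pool individual stripes (each stripe
one observation), which reproduces the larger spread of multi-stripe
categories; per-record averaging was compared and gives smaller sds.
Classification is invariant under cyclic shifts.

## What the tests establish, and known limitations

* The 1D machinery reproduces published behavior quantitatively at
  publication scale (10⁴ random ICs): stripe-category percentages at
  (3.5, 2.2, 1e-3) within a few tenths of a percentage point, and pooled
  single-stripe widths at four parameter sets within ~0.2%.
* The 2D occupancy figures (95%/84%/78% at c₂ = 1.0/1.05/1.1) are **not**
  reproduced: under every protocol constructible from the published
  description (per-site random ICs with either law, either δ convention,
  D = 0, nested-square ensembles, biomass-share accounting) the CDI−
  occupancy stays ≥ 98% at those inhibition values, crossing 95% → 78%
  only around c₂ ≈ 1.17–1.25.  The 2D random-IC protocol appears
  underdetermined by the text; the corresponding acceptance test is left
  failing by design rather than fitted.
* With on-site-only inhibition (the `kernel="onsite"` control) the
  kernel-driven share of the CDI− space advantage disappears (occupancy
  drops from ~0.77 to ~0.66 at the reference point); the residual
  asymmetry comes from the initial-condition law, not the interaction
  range, so "equal occupancy" holds only relative to that baseline.
* Converged ensemble states are frozen to machine-level drift under the
  stated convergence rule; genuinely marginal configurations near phase
  boundaries could in principle evolve on timescales beyond the 3e5 cap,
  but none were observed (zero unconverged runs across ~5×10⁴ ensemble
  integrations).
* Stochastic (demographic-noise) variants and growth-phase-dependent CDI
  expression are out of scope.
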