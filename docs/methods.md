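# Methods

## The model

`rrlogistic` simulates a single-species population in a square habitat patch
of side `L` (area `A = L²`) with periodic boundaries.  Each organism `i`
carries a home-range centre `μᵢ` and a position `xᵢ(t)`, and three processes
act on the population:

**Movement.**  Between demographic events every organism moves.  The default
is range residency, modelled by an Ornstein–Uhlenbeck (OU) process

    dx = −(x − μ)/τ dt + √(2 σr²/τ) dW,

with home-range crossing time `τ` and stationary per-component variance
`σr²`; the long-run space use is an isotropic Gaussian of variance `σr²`
around the centre.  Two limits are implemented as their own modes rather
than as extreme parameter values: `BM` (uniform space use; `τ, σr² → ∞`
with `D = σr²/τ` fixed, plain Brownian motion with stationary law uniform
on the torus) and `SESSILE` (`D = 0`; organisms sit where they settle at
birth, which recovers the classic sessile spatial logistic
individual-based model).

**Birth and dispersal.**  Constant per-capita birth rate `b`.  An
offspring's home-range centre is displaced from the parent's by a draw from
the dispersal kernel — Gaussian with per-component standard deviation `σd`
by default (dispersal distance Rayleigh(σd)), or a Gamma-distributed
distance with uniform direction as a robustness variant.  The offspring's
initial position is a draw from its stationary space-use law (it is assumed
to relax to steady-state movement immediately).

**Death by competition.**  Organism `i` dies at rate

    dᵢ = d0 + γ Σ_{j≠i} Kc(xᵢ − xⱼ),

where `Kc` is an isotropic bivariate Gaussian of scale `σq`, truncated at
`2.45 σq` (which retains `1 − exp(−2.45²/2) ≈ 95%` of its mass), and
displacements use the minimum-image convention on the torus.

The dynamics are simulated exactly with the Gillespie algorithm: rates are
computed from current positions, an exponential waiting time is drawn, all
organisms are propagated over it with the *exact* transition law of their
movement process, and then birth or death is executed with the pre-move
rates.  Exact transition sampling (rather than Euler stepping) is
unconditionally stable for the widely varying inter-event times the
algorithm produces; the choice to execute the event with pre-move rates
keeps the sampled waiting time and the event probabilities mutually
consistent, and the alternative order (event before movement) is available
behind the `order` flag of the reference stepper — the two agree to first
order in the waiting time.

## Theory: crowding and carrying capacity

At first order in spatial moments the mean density `n = N/A` obeys

    dn/dt = b n − d0 n − γ c(t) n²,

where the crowding index

    c(t) = ∫ Kc(u) g₂(u, t) du

weights the pair correlation function `g₂` by the competition kernel.
`c = 1` for homogeneous (CSR) populations, recovering the Verhulst
equation; `c > 1` means overcrowding at the competition scale.  The
non-trivial equilibrium is the carrying capacity

    n* = (b − d0)/γ · 1/c* = n_CSR*/c*,

so the normalised capacity `n*/n_CSR*` equals the inverse equilibrium
crowding — purely spatial information predicts population size.  The
covariance-convention index used by classical neighbourhood-competition
models is related by `c_cov = n²(c − 1)`.

For range residents whose crossing time is short relative to demographic
timescales (`τ (b + d0) ≪ 1`), crowding can equivalently be computed from
home-range *centres* with the composed kernel `K_HR`: the competition
kernel averaged over both organisms' stationary space use, i.e. an
isotropic Gaussian of per-component variance `σq² + 2σr²` (each organism
contributes `σr²` to the displacement variance).  This identifies the
range-resident model with a sessile spatial logistic model whose kernel is
the stationary displacement distribution, and is validated in the tests by
a Monte-Carlo convolution oracle.

## Estimators

Both crowding estimators are pair sums over minimum-image displacements
normalised by the number of *ordered* pairs `N(N−1)` and by the kernel mass
retained on the torus, so their CSR expectation is exactly 1 at any finite
`N` (not just asymptotically):

* positions: `c = A/(N(N−1)) Σ_{i≠j} K̃c(xᵢ − xⱼ)` with `K̃c` the truncated
  kernel divided by its retained mass (0.9503 at the default truncation);
* home ranges: the same sum over centres with the composed kernel, which is
  *not* truncated (the weighting function is defined by the stationary
  displacement distribution, not by the simulation cut-off); it is summed
  over enough periodic images that the lattice sum is converged, and
  renormalised by its exact mass on the torus (an erf² expression).  The
  residual difference from the truncated-kernel convention is far below
  estimator noise, and shows up only as a percent-level offset between
  `c_pos` and `c_HR` on strongly clustered patterns.

The pair correlation function is estimated isotropically on the torus as
(ordered pairs in an annulus)/(annulus area), scaled by `A/(N(N−1))`; no
edge correction is needed under periodic boundaries.  Bins must lie within
`(0, L/2]`, where torus annuli are complete.

A caveat for cluster processes: conditioning on the realised `N(N−1)`
makes the per-pattern ratio estimator biased high relative to the
process-level index when `E[N]` is small, because for a Poisson cluster
process `E[N(N−1)] = λ²A²(1 + 1/(κA))`.  The test-suite therefore checks
the *unconditional* pair-sum expectation against the closed-form Thomas
pair correlation function, which is exact at any intensity.

## Default study conditions

All defaults are the study conditions used throughout: `L = 1` (periodic),
`b = 1.5`, `d0 = 0.1`, `γ = 0.002` (so `n_CSR* = 700`), kernel truncation
multiplier 2.45, initial condition 700 uniformly placed organisms at their
stationary positions, and a fixed event budget with the end-state snapshot
taken as the quasistationary sample.  Simulated capacities are normalised
by `n_CSR*/0.95` to compensate the interaction rate lost to kernel
truncation; the truncated kernel is *not* renormalised inside the death
rate, which is what makes that compensation the right one.

Parameters that matter and their units (lengths in units of `L`, rates per
unit time):

| parameter | meaning | default |
| --- | --- | --- |
| `b`, `d0`, `γ` | birth, baseline death, competition strength (rate·area) | 1.5, 0.1, 0.002 |
| `σq` | competition-kernel scale | 0.01 |
| `σd` | dispersal scale (Rayleigh mode of the distance) | study-dependent |
| `τ`, `σr²` | OU crossing time, home-range variance | study-dependent |
| `trunc_mult` | kernel truncation radius in units of σq | 2.45 |
| `events` | Gillespie event budget | 10⁶ (full), 2×10⁵ (sweeps) |
| `burn_in` | fraction of the series discarded for time averages | 0.5 |

Home-range "size" in sweep outputs is reported both as raw `σr²` and as the
95% Gaussian home-range area `−2π σr² ln(0.05)`, since either convention is
common.  The transect that varies home-range size does so by increasing `τ`
at fixed diffusion `D` (`σr² = D τ`).

The Gamma-distance dispersal variant uses shape `k = 3` by default with the
scale set so the mean dispersal distance equals the Gaussian kernel's
Rayleigh mean `σd √(π/2)`, making kernels comparable at fixed mean
dispersal distance.

## Numerical choices

* **Exact OU sampling.**  `x' = μ + (x − μ) e^(−Δt/τ) + ε` with
  `ε ~ N(0, σr²(1 − e^(−2Δt/τ)))`, verified against Euler–Maruyama
  integration of the SDE.  Positions are *not* wrapped during propagation
  (wrapping an OU path would corrupt the reversion bookkeeping); centres
  are wrapped at birth and all interactions wrap on demand.
* **Minimum image and ties.**  Displacement components lie in
  `[−L/2, L/2)`; exact half-box ties resolve to `−L/2` for determinism.
* **Kernel on the torus.**  Truncation is applied to the minimum-image
  distance.  When the truncation radius reaches `L/2` (very long-range
  competition) the Gaussian is summed over periodic images out to 8σq per
  axis via separable 1-D sums; for `σq` comparable to `L` this lattice sum
  is numerically flat at `1/A`, which is how the well-mixed limit is
  exercised in the tests.
* **Neighbour search.**  Death rates are recomputed per event through a
  cell list with cell size ≥ the truncation radius (capped at 64×64 cells);
  in sessile mode positions never change, so rates are maintained
  incrementally — the increment added at a neighbour's birth cancels
  bitwise at its death.  A brute-force all-pairs path is kept as the test
  oracle for both.
* **Engine/reference parity.**  The jitted engine and the pure-NumPy
  reference stepper consume a single RNG stream in an identical draw order
  (waiting time → per-organism movement noise → event choice → event
  draws), so entire event sequences can be compared across implementations;
  runs are bit-reproducible given a seed, and sweep replicates derive seeds
  from a splittable seed sequence keyed by (master seed, cell, replicate).
* **Capacity management.**  The engine works in preallocated slot arrays
  sized from `n_CSR*`; if a trajectory outgrows them it pauses *before*
  consuming any draws, the arrays are enlarged, and the run resumes on the
  same stream, so results are independent of the allocation.
* **Degenerate inputs.**  Crowding and pair-correlation estimators require
  `N ≥ 2`; an empty initial population returns an immediately-extinct
  result; extinction inside a run is absorbing and recorded.

## What the synthetic data emulate — and what they do not

The fixture generators (`csr`, `thomas`, `lattice`, `two_point`) produce
point patterns with known second-order structure: CSR pins the `c = 1`
reference, the Thomas cluster process has a closed-form pair correlation
`1 + exp(−r²/(4σc²))/(4πκσc²)` against which both the crowding index and
the pair-correlation estimator are checked, and the lattice/two-point
patterns give exact pair-count arithmetic.  The simulator itself is the
generator for quasistationary patterns.

Everything is stationary, isotropic and homogeneous: there is no habitat
heterogeneity, no movement interaction between organisms (avoidance,
territoriality), no parameter variation between individuals, and dispersal
and competition are radially symmetric.  Passing tests therefore
demonstrate the internal consistency of model, estimators and theory under
these idealisations — not that any particular field population satisfies
them.  Applying the home-range crowding index to tracking data additionally
requires estimated `σr²` per animal (supported by the per-organism
interface) and trust in the `τ(b + d0) ≪ 1` timescale separation.

## Problem sizes used in the checks

The automated checks run at desk scale: sweeps use grids of a few cells
with 2–5 replicates of 0.6–2.5 × 10⁵ events (sessile cells, which
equilibrate more slowly but run faster, get the larger budgets), while the
sessile-uplift quantity in the acceptance script uses 5 replicates of 10⁶
events.  Full-scale sweeps (20 replicates, 10⁶ events, decade-spanning
grids) are available through the same `SweepConfig`/CLI machinery.  At
reduced scale the predicted-vs-measured analysis is checked against an
R² ≥ 0.9 threshold rather than a point value, since the attainable R²
depends on the grid and replicate count.

## Known limitations

* Second-order spatial-moment closures are out of scope; the theory here is
  first order with crowding measured, not predicted, from snapshots.
* Very small competition scales (`σq ~ 10⁻³`) put the model in a regime of
  near-singular pairwise rates where the mean-rate theory degrades; the
  predicted-vs-measured analysis deliberately exercises the moderate-scale
  regime.
* The per-pattern crowding estimator carries an `O(1/E[N])` conditioning
  bias on strongly clustered patterns (see above); at the study's
  `N ≈ 700` this is negligible.
* Movement modes with autocorrelated velocity, behavioural switching, or
  attraction/avoidance are not implemented.
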