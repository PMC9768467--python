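# Methods

## Model and assumptions

`rfmnet` implements the deterministic mean-field description of ribosome
traffic. Each mRNA is a chain of `n` coarse-grained sites (each site a
group of consecutive codons) with occupancies in [0, 1]; the flow from
site `j` to `j+1` is `lambda_j * x_j * (1 - x_{j+1})` — proportional to
the upstream density and the downstream free space, a soft form of the
exclusion principle. All rates are strictly positive (enforced at
construction) and carry units of 1/s; occupancies and densities are
dimensionless. The model ignores ribosome drop-off and attachment along
the chain, direct mRNA–mRNA interactions, and stochastic fluctuations:
chains interact *only* through the shared pool, whose output functions
`G_i` (monotone, `G_i(0) = 0`) scale each chain's initiation rate.

The key structural facts the solvers rely on:

* an isolated chain driven at constant input has a unique globally
  attracting equilibrium, recoverable from the Perron eigenpair of a
  symmetric nonnegative tridiagonal matrix built from the reciprocal
  square roots of the rates, with production rate `R = sigma**-2`;
* the pool-coupled network conserves the total density `s` and each
  level set of `s` contains exactly one attracting equilibrium.

## Numerical choices

**Spectral solve.** The largest eigenpair comes from
`scipy.linalg.eigh_tridiagonal` on the off-diagonal vector (selecting the
top index only); a dense `eigh` on the assembled matrix is the fallback
if the tridiagonal path fails. The eigenvector is normalized to unit
Euclidean length with positive sign; the occupancy formula uses only
ratios of consecutive entries, so the normalization is immaterial (some
presentations fix the last entry to 1 instead). The adopted index
convention `e_i = zeta_{i+2} / (lambda_i**0.5 * sigma * zeta_{i+1})` is
validated in the tests against both the two-site closed forms and the
ODE oracle; it is the only reading consistent with `R = sigma**-2` and
flow balance.

**ODE relaxation.** `relax_to_steady_state` integrates the chain with
LSODA (`rtol 1e-12`, `atol 1e-14`) over doubling horizons until the
vector-field max-norm falls below `tol` (default `1e-10`), erroring out
at a horizon cap of 1e7 s of model time. States are clipped to [0, 1]
inside the right-hand side: the cube is forward-invariant for the exact
flow, so clipping only guards against integrator overshoot at the
boundary. `u = 0` short-circuits to the empty chain.

**Network equilibrium.** The first integral reduces the fixed point to
one unknown. `D(e_z) = e_z + sum_i (chain density at input G_i(e_z))` is
continuous and strictly increasing with `D(0) = 0 < s` and `D(s) > s`,
so Brent's method on `[0, s]` (absolute tolerance `1e-12 * max(s, 1)`)
finds the unique root. Chains are stored as *groups* (profile, pool
function, copy count): each `D` evaluation costs one spectral solve per
distinct group, which is what makes copy numbers of 1e5 instantaneous.
A root at exactly `e_z = 0` (possible only in degenerate floating-point
corner cases) yields empty chains with zero production.

**Network simulation.** `simulate` integrates the coupled system with
LSODA at `rtol 1e-11 / atol 1e-13` — tight, because the acceptance
contract bounds the drift of the conserved density along the sampled
trajectory by `1e-6 * s` — over doubling horizons until the residual
max-norm is below `tol` (default `1e-8`), warning (not failing) at the
horizon cap. The default initial condition places the whole density in
the pool; an initial state whose density mismatches `s` is rejected
unless `rescale=True`, which scales the state onto the level set and
dumps any clipping remainder into the pool.

**Assumption audit.** The starved-pool limits require initiation rates
bounded below, exit rates bounded above, and a uniform linear lower
bound `G_i(z) >= g z` near zero. `audit_assumptions` evaluates `G(z)/z`
on a log-spaced grid down to `1e-12 p` and rejects a bound below `1e-9`
of the secant slope `G(p)/p` — this catches functions like `z**3` whose
grid minimum is positive but whose infimum is zero. For concave outputs
(e.g. tanh) the reported `g` is the secant `G(p)/p`, the tightest valid
slope.

**Reduction convention.** Collapsing `m` identical chains with linear
pool output `G(z) = g z` to a single one-site chain constrains only the
product `lambda0_bar * g_bar = lambda_0 * g * m` and the exit rate
`1/lambda1_bar = sum_j 1/lambda_j`. We fix `g_bar = g` and fold the copy
number into `lambda0_bar`. The reduction preserves the *asymptotic*
`TPR/e_z` and `q`; at finite `s` the two networks differ — agreement to
1% requires a genuinely starved pool (empirically `e_z/s` of order 1e-3
for the yeast-rate example, reached around `s = 0.002` at `m = 50`).

**Calibration.** For the cell-free pipeline the linear coupling slope
`c` is chosen so the effective initiation rate is maximal while staying
the bottleneck: `lambda_0 * c * e_z(c) = min(lambda_1..lambda_n)`. The
left side is increasing in `c`, so an expanding bracket plus Brent
applies. The product is capped by the density constraint (as `c` grows,
`e_z` shrinks); if `s/m` is below the chain density the bottleneck point
requires, the equation is infeasible and a diagnostic error reports the
achieved value.

**Convergence bookkeeping.** "Eventually decreasing" error columns are
checked over the last half of a schedule — convergence to the limits is
asymptotic and need not be monotone from the first grid point. A
schedule that fails to deplete the pool triggers a warning and no
convergence claim.

## Synthetic decoding-time generator

`synthesize_decoding_times` emulates the input of the coarse-graining
pipeline: per-codon decoding times drawn i.i.d. log-normal with
arithmetic mean 0.4 s and log-scale 0.35 (defaults), so a 10-codon site
has an unnormalized rate near 0.25 1/s — the scale of coarse-grained
yeast decoding-rate estimates. It is a synthetic stand-in for
ribo-seq-derived rate profiles and reproduces none of their real
structure: no codon-identity effects, no 5' ramp, no autocorrelation
along the transcript. Tests passing on these profiles therefore validate
the *pipeline algebra* (grouping, reciprocal sums, the single global
normalization factor, calibration) and the model's structural claims,
not any statement about a particular gene. Site rates are normalized by
one common factor so the mean per-codon rate (site rate × codons in the
site, averaged over sites) equals 10 codons/s, a typical eukaryotic
decoding speed; normalization is applied after coarse-graining and never
touches the user-supplied initiation rate, which is not derivable from
decoding times. Both choices are exposed as parameters.

## Problem sizes used in the checks

The test suite solves: the homogeneous two-site network up to m = 1e5
chains; copy-number sweeps to m = 100 for one homogeneous and ten random
heterogeneous families; the yeast-rate identical-chain network over
m = 1 to 1000 at s = 20; 50 random chains (n ≤ 8) for the spectral/ODE
cross-check and 20 random networks (m ≤ 5, n ≤ 6) for the
simulation/root-find cross-check. These sizes probe the starved regime
(e_z down to ~1e-4) while keeping the whole suite under a minute of
compute; all scaling claims are asymptotic statements the schedules
approach, not exhaust.

## Known limitations

* Sensitivity and optimization of `R` with respect to the rates are out
  of scope (only midpoint concavity of `R` is property-tested).
* Closed-form starved-pool expressions for *subsets* of chains exist but
  are not implemented; the network-level forms are.
* Stochastic (TASEP) dynamics, ribosome drop-off/attachment, and direct
  context-dependent mRNA coupling are not modelled.
* `simulate` expands chain groups and is intended for small networks
  (it refuses m > 10 000); the equilibrium solver has no such limit.
* Custom pool functions cannot be serialized to config files.
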