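# Methods

## Model

A single target cell infected by one virion passes through an eclipse
phase of `n_E` exponential stages (Erlang mean `tau_E` absent killing) and
an infectious phase of `n_I` stages (mean `tau_I`).  The immune system
removes eclipse cells at rate `nu_E` and infectious cells at rate `nu_I`;
virus-induced death occurs on exit from the last infectious stage.  Each
stage exit is a race of independent exponentials, so the per-stage
survival probabilities are `r_E = delta_E/(delta_E+nu_E)` and
`r_I = delta_I/(delta_I+nu_I)` with `delta = n/tau`, and the number of
infectious stages survived, K, has the closed distribution implemented in
`burst.stage_count_pmf`.

Two release mechanisms share this lifetime structure:

* **budding** — virions are released one at a time at rate `p` while the
  cell is infectious.  Conditioned on K = k, the burst size B counts
  release events before the k-th stage exit, i.e. B | K=k is negative
  binomial with shape k and success probability `p/(p+delta_I+nu_I)`; the
  p.m.f. of B is the K-mixture.
* **bursting** — virions accumulate intracellularly at rate `p` and are
  released only at virus-induced death after stage `n_I`; immune killing
  destroys the stock.  B is a zero-inflated negative binomial: burst
  probability `r_E^{n_E} r_I^{n_I}`, shape `n_I`.

When `nu_I = 0` the two mechanisms give identical distributions; the
difference between budding and bursting is entirely an interaction with
immune killing.

Secondary infections: with a constant target pool (Case 1) each virion
independently infects with probability `theta = beta*T0/(c+beta*T0)` and
the p.m.f. of the reproduction number R equals the burst-size p.m.f. with
`p -> theta*p`.  With a depleting pool (Case 2) virions are processed
sequentially through the thinning chain with success probability
`xi_i = beta*(T0-i)/(beta*(T0-i)+c)` after i infections; the p.m.f. of R
mixes the chain kernel over the burst distribution.  Case 2 considers
depletion by the focal cell's own virions only, not by virions from
secondary cells; neither case models target-cell regeneration.

Extinction: under Case 1 the infected-cell lineage is a Galton-Watson
process with offspring distribution R, so the extinction probability from
one cell is the smallest fixed point in [0, 1] of the offspring p.g.f.,
and from i independent cells it is that value to the power i.

## Parameters

| name | meaning | units | default |
|------|---------|-------|---------|
| p | release (budding) / production (bursting) rate | virions/(cell day) | 1000 |
| tau_I | mean infectious period absent killing | days | 1.25 |
| n_I | infectious Erlang stages | – | 10 |
| nu_I | immune clearance of infectious cells | /day | varied (0–1.6) |
| tau_E, n_E | eclipse Erlang mean / stages | days, – | inert (nu_E = 0) |
| nu_E | immune clearance of eclipse cells | /day | 0 |
| beta | infection rate | /(cell virion day) | 1e-4 |
| c | extracellular virion loss | /day | 7 |
| T0 | initial target cells | cells | 1e5 |

The defaults are the baseline in-vivo-scale parameter set used by every
scenario preset.  With `nu_E = 0` every infected cell survives the
eclipse phase, so `tau_E`/`n_E` influence nothing that this package
computes; they are accepted but flagged inert.  All rates are per day; no
unit conversion layer is provided.

## Numerical choices

* **Truncation.**  Burst-size and R supports are unbounded; p.m.f.s are
  truncated at the smallest support containing all but `1e-12` of the
  mass (grown geometrically from the widest mixture component's negative
  binomial quantile), with a configurable hard cap of 1e6 and the
  remaining mass recorded as `tail_mass`.  Exceeding the cap raises
  `TruncationError` rather than silently renormalising.
* **Negative binomial terms** are evaluated through `scipy.stats.nbinom`
  (log-gamma based), so shape up to ~50 and counts up to ~1e6 neither
  overflow nor underflow term-by-term.
* **Budding mean with weak killing.**  The closed form
  `(1 - r_I^{n_I}) p/nu_I` cancels catastrophically as `nu_I -> 0`; it is
  evaluated via `expm1`/`log1p`, and below `nu_I/delta_I = 1e-12` the
  exact `p tau_I` limit branch is used (relative difference from the
  exact expression is O(1e-12) there).
* **Case 2 evaluation order.**  The thinning-chain occupancy vector is
  rolled forward one virion at a time and accumulated against the burst
  p.m.f., giving O(b_max · min(b_max, T0)) time and O(min(b_max, T0))
  memory; the b-sum reuses the burst truncation point.
* **Fixed points.**  Criticality is decided from the closed-form mean
  (extinction probability is exactly 1 when the mean is <= 1), never from
  the solver.  The supercritical fixed point is found by functional
  iteration from s = 0, which for a p.g.f. converges monotonically to the
  smallest fixed point, with tolerance 1e-14, an iteration cap of 1e6 and
  a bisection fallback.
* **Hellinger comparisons** zero-pad the shorter support and refuse
  operands whose truncation tails exceed 1e-9.

## Simulator

The simulator is an independent oracle, deliberately avoiding the mixture
algebra of the analytic modules:

* `sample_burst_sizes` walks the embedded jump chain stage by stage
  (geometric release counts per stage for budding; realised Erlang
  lifetimes with a Poisson(p·lifetime) burst for bursting — production
  events are independent of lifetime events, so deferring the Poisson
  draw to the burst instant is distributionally exact).
* `thin_to_infections` performs binomial (Case 1) or sequential (Case 2)
  thinning.
* `run_ctmc` is an exact Gillespie direct-method simulation of the full
  system-level Markov chain (infection, stage progressions, killings,
  release, virion loss).  In the bursting variant each infectious cell is
  an agent carrying its infectious-phase entry time; its burst is a
  single state jump adding a Poisson(p · realised lifetime) count to the
  free-virion pool at the death event.  A lineage is scored extinct when
  free virions and infected cells are all zero; supercritical runs can be
  stopped early once cumulative infections reach an establishment
  threshold (default 150 in `extinction_frequency`; at the parameter
  regimes tested the probability that a lineage with 150 infections dies
  out is below 1e-9, so the bias is far below Monte-Carlo noise).

One master seed drives everything; per-replicate generators are derived
from it, so any replicate count is exactly reproducible.

What the simulator does *not* emulate about real data: virions here are a
homogeneous well-mixed pool (no spatial structure, no cell-cell
transmission, no multiplicity of infection), production rates are
constant over a cell's infectious phase, and the immune clearance rates
are fixed constants rather than a dynamic response.  Agreement between
simulation and the analytic p.m.f.s therefore validates the derivations
and the code, not the biological realism of the model class.

Simulation-backed tests run at reduced production rates (p ≈ 25–40) and
3–10 stages so that supports stay in the hundreds and event counts in the
millions; the distributional identities being checked are
scale-invariant, and the closed-form references are always recomputed at
the same reduced parameters.

## Scenario presets

The `virodyn` CLI reproduces the numerical experiments as data tables:
Case 1 vs Case 2 comparisons for four (theta, T0) panels and a Hellinger
grid over (beta, T0); R p.m.f.s over `nu_I in {0, 0.25, 0.5, 1, 1.6}` for
both models; extinction versus initial dose; bursting p.m.f.s over
`n_I in {1, 5, 10, 25, 50}` at `nu_I = 1.6`; and extinction versus theta
and versus `n_I` (tau_I held fixed, so `delta_I` is recomputed at each
grid point).  Where a published panel fixes theta without printing beta,
the preset solves `beta = c*theta/((1-theta)*T0)` so that any (theta, T0)
pair can be realised exactly.  Plotting is optional (`--plot`); the CSV
tables are the tested surface.

## Known limitations

* Case 2 extinction probabilities are out of scope: the branching
  argument requires a constant target pool.
* Extinction probabilities are asymptotic (eventual) only; no
  time-to-extinction distributions.
* The depletion chain ignores competition from virions produced by
  secondary infected cells.
* Age-dependent (non-constant) release rates are not modelled.
* `n_I` beyond ~50 with means beyond ~1e5 pushes supports toward the
  truncation hard cap; raise `hard_cap` explicitly for such regimes.
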