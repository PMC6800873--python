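# Methods

## Model family and assumptions

The package constructs deterministic mean-field ODE models for continuous
time state-transition systems in which a focal state X is partitioned
into sub-states X₁…X_n whose dwell times are first-event times of
independent (possibly nonhomogeneous) Poisson processes with rates
rᵢ(t).  A particle leaving X_i at time t moves to X_j with probability
p_ij(t) or to a recipient state Y_ℓ with probability p_{i,n+ℓ}(t); rows
of [P_X | P_Y] must sum to one at every time.  Inflow enters the
sub-states either directly (𝓘_{X_i}(t)) or as a scalar rate split by an
entry distribution ρ(t).  The mean-field equations are

    dx/dt = 𝓘_X(t) + P_X(t)ᵀ(R(t)∘x) − R(t)∘x.

Each named builder realizes a dwell-time family as a particular sub-state
topology on top of this form:

| builder | dwell time | sub-states |
|---|---|---|
| `build_lct_chain` | Erlang(r, k) | chain of k, rate r |
| `build_extended_chain` | k-th event time, rate r(t) | chain of k, rate r(t) |
| `build_proportional_outputs` | as above, recipients split p_ℓ(t) | chain of k |
| `build_mixture` | finite mixture, weights ρᵢ(t) | N parallel chains |
| `build_competing` | min of n event times | product lattice, Πkᵢ states |
| `build_intermediate_reset` | base min + independent intermediate chains | lattice + Erlang chains |
| `build_intermediate_preserve` | base min, total dwell preserved | lattice + slot-entry chains |
| `build_series` | sum of event times | concatenated chain, Σkᵢ states |
| `build_max` | max of Erlangs (constant rates) | marked lattice, Π(kᵢ+1)−1 states |

For constant parameters the dwell time in X is a phase-type
distribution; `glct_from_phasetype` turns any (ρ, G_X, G_Y)
representation into the equivalent model, and the X-block right-hand
side then equals 𝓘 + G_Xᵀx identically (a property test asserts this to
round-off on random representations).

Two modeling subtleties deserve emphasis:

* **Competing routing.**  On the event lattice every sub-state loses mass
  at the summed rate r(t) = Σrᵢ(t); the probability that the event
  belongs to process i is rᵢ(t)/r(t).  Where r(t) = 0 this ratio is
  undefined; the implementation substitutes an equal split there, which
  is immaterial because the associated flow is zero.
* **Reset vs preserve.**  An intermediate within-X transition (e.g.
  hospitalization during infection) either restarts the dwell clock
  (independent Erlang(ϱⱼ, κⱼ) chains) or preserves it.  Preservation
  exploits the weak-memorylessness of first-event times: a particle that
  leaves the base lattice while awaiting event a₀ = j of the exit
  process enters intermediate slot j, so it still awaits events j…k₀ at
  rate r₀(t) and the total X dwell time remains the k₀-th event time,
  regardless of the competing rates and routing.  The invariance test
  perturbs those by ±50% and requires the survival curve to move by less
  than 10⁻⁶ in sup norm.

## Recipient states

Recipients with exponential (rate μ(t)) or Erlang(μ, κ) dwell are
appended to the ODE system (the Erlang case as its own chain).  A
recipient with an arbitrary survival function S_Y(t, τ) is *not* coupled
into the solve; its occupancy

    y(t) = y(0) S_Y(t, 0) + ∫₀ᵗ (𝓘_Y(τ) + influx(τ)) S_Y(t, τ) dτ

is evaluated post hoc by trapezoid quadrature on the stored influx
series (`evaluate_recipient_integral`), so its accuracy is set by the
output grid spacing — with ~2000 points on a 10-unit horizon the error
against the ODE-appended equivalent is below 10⁻⁴.  Full Volterra
coupling of generic recipients back into the dynamics is out of scope.

## Numerical choices

* **Survival evaluators** use the u-kernel u^k(m) = m^{k−1}e^{−m}/(k−1)!
  with m(τ, t) = ∫ r, computed in log space (via `gammaln`) so shapes in
  the hundreds neither overflow nor lose normalization; the density is
  r(t)·u, which stays defined where r(t) = 0.
* **Cumulative rates**: closed forms for the constant, sinusoidal and
  piecewise-linear rate vocabulary; adaptive quadrature (`scipy` quad,
  absolute tolerance 10⁻¹⁰) for arbitrary callables.  Tests deliberately
  cross the two routes (closed-form model vs quadrature oracle).
* **Integration**: `solve_ivp` with DOP853, defaults rtol 10⁻⁸ /
  atol 10⁻¹⁰; identity checks tighten to 10⁻¹⁰–10⁻¹² where a 10⁻⁷
  agreement is asserted.  These systems are smooth and non-stiff by
  construction (rates within a few orders of magnitude), so a high-order
  explicit method is both faster and more accurate here than a stiff
  solver.
* **Matrix exponentials**: `scipy.linalg.expm` (scaling-and-squaring with
  Padé), cross-checked against ODE integration of the same generator.
* **Validation**: representation invariants (row sums, sign patterns,
  probability normalization) are checked at tolerance 10⁻¹² for constant
  matrices and 10⁻⁹ for time-varying routing sampled at grid points;
  invalid inputs are rejected, never repaired.
* **Impulse inputs** are realized as initial conditions (mass placed by
  the entry distribution ρ), never as Dirac terms in the right-hand
  side; `survival_from_model` uses this convention to read off the
  implied dwell-time survival as the total-X occupancy.
* **Moment matching**: a gamma target (μ, σ²) is made Erlang by rounding
  the shape μ²/σ² to an integer (nearest/floor/ceil, clamped to ≥ 1) and
  re-deriving the rate as k/μ, so the mean is preserved exactly and the
  variance moves to μ²/k.
* **Index ordering**: lattice states are enumerated row-major
  lexicographically with the first coordinate slowest, labels
  `X_(a1,…,an)`; the ordering is a convention only, all quantities are
  label-addressed.
* **Time-varying routing and weights** are evaluated at the current ODE
  time; for entries occurring at time t this coincides with evaluating
  the entry-time-indexed weights of the integral formulation.

## Stochastic oracle

`simulate_ensemble` runs an exact event-driven simulation of the labeled
jump process: exponential waiting times for constant rates, Ogata
thinning for time-varying ones (the automatic bound is 1.5× the maximum
of r on a 1000-point grid — a heuristic; supply exact bounds when
available).  Per-particle random streams are spawned from the master
seed by particle index, so results are independent of execution order
and byte-reproducible.  Occupancy is recorded right-continuously on the
output grid; recipients are absorbing in the simulator, so comparisons
use ODE models with sink recipients.

What the simulator *does* establish: that every builder's ODE system is
the large-population limit of the stochastic process it claims to
represent, with sup-norm occupancy discrepancy decaying at the
Monte-Carlo rate (the log-log slope across n ∈ {10³, 10⁴, 10⁵},
averaged over three replicate ensembles per size to tame the noise of
the sup statistic, is required to lie in [−0.65, −0.35]).  What it does
not: anything about fit to real data — the package constructs models
from assumptions; estimating those assumptions from data (e.g. fitting
phase-type distributions) is explicitly out of scope and deferred to
external tools.

## Synthetic fixtures

`fixture_random_glct` draws always-valid random models: rates
log-uniform on [0.1, 10] (a realistic span of per-capita rates once time
is measured in units of a typical dwell), routing rows from a flat
Dirichlet simplex, entry distribution likewise, and optionally a bounded
sinusoidal rate modulation r(1 + 0.5 sin(ωt + φ)) with ω ∈ [0.5, 2] —
seasonal-scale forcing relative to the dwell scale.  These fixtures
exercise validation, the generator correspondence, and non-negativity
along trajectories; they do not emulate any particular empirical system.

## Problem sizes and scope of the verification

Verification runs use chains up to shape 8 (plus a shape-150 stability
check of the evaluators), lattices up to 2×3×2, random phase-type
representations up to n = 5 transient states, 200–400-point output
grids, and ensembles up to 10⁵ particles; all checks are deterministic
given the seed.  Known limitations: no symbolic simplification or
minimal-order realization of the generated systems; no delay-equation
representations; phase-type evaluators require time-homogeneity
(time-varying cases are handled by the ODE builders only); weak
memorylessness — and therefore the preserve construction — applies to
first-event (not k-th event) remaining times, which is why intermediate
chains track the event index rather than elapsed time.
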