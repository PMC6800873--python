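# glct — mean-field ODE models from dwell-time assumptions

`glct` builds systems of mean-field ordinary differential equations
mechanically from individual-level stochastic assumptions, using the
**linear chain trick** (LCT) and its generalizations (GLCT).  It is aimed
at modelers in epidemiology, ecology and pharmacokinetics who want
compartmental ODE models whose dwell-time distributions are *explicit
modeling choices* — Erlang, time-varying event times, mixtures, competing
risks, maxima, sums, or general phase-type distributions — rather than the
exponential distribution silently implied by a per-capita rate constant.

## The idea

If the time a particle spends in a state X is Erlang(r, k) distributed
(a gamma with integer shape — equivalently the k-th event time of a
Poisson process with rate r), X can be partitioned into k sub-states
X₁ → X₂ → … → X_k, each with an exponential(r) dwell, giving linear ODEs

    dx₁/dt = 𝓘(t) − r x₁,    dx_j/dt = r x_{j−1} − r x_j,

whose total occupancy Σⱼ xⱼ(t) under an impulse input reproduces the
Erlang survival function S_r^k(t) exactly.  The generalized form handles
any configuration of sub-states with Poisson first-event dwell times:
given per-sub-state inflows 𝓘_X(t), rates **R**(t), and routing matrices
**P**_X(t) (within X) and **P**_Y(t) (out to recipient states),

    d**x**/dt = 𝓘_X(t) + **P**_X(t)ᵀ(**R**(t)∘**x**) − **R**(t)∘**x**,

with ∘ the elementwise product.  For constant parameters this is exactly
a phase-type dwell time — the absorption time of a CTMC with initial
distribution ρ and subgenerator **G**_X — and the X block reduces to
d**x**/dt = 𝓘(t) + **G**_Xᵀ**x**, with density f(t) = ρᵀe^{t**G**_X}(−**G**_X𝟏).

The package provides:

* `distributions` — closed-form evaluators (Erlang, nonhomogeneous
  event times, mixtures, competing minima, maxima) used as analytic
  oracles, plus Erlang moment matching;
* `phasetype` — the three CTMC parameterizations (rate/routing, embedded
  jump, generator), conversions, and phase-type pdf/CDF via `expm`;
* `builders` — one constructor per dwell-time family, each returning a
  labeled `ODESystem` (including clock-resetting vs clock-preserving
  intermediate sub-state transitions, e.g. hospitalization that must not
  change the overall infectious period);
* `simulate` — ODE integration, survival extraction, exact dwell-time
  samplers and an event-driven particle simulator as independent oracle;
* `models` — Erlang-SIR and phase-type SIR constructors, random fixtures;
* `io`/`cli` — a declarative YAML/JSON model-spec schema and a `glct`
  command-line tool (`build`, `survival`, `simulate`, `ensemble`,
  `fixtures`).

## Worked example

```python
import numpy as np
from glct import (ErlangParams, build_lct_chain, erlang_survival,
                  survival_from_model, SIRParams, sir_erlang, integrate)

# 1. chain-trick survival identity
p = ErlangParams(rate=0.5, shape=4)        # mean 8, cv 0.5
sys = build_lct_chain(p)
t = np.linspace(0.0, 30.0, 301)
surv, dens = survival_from_model(sys, t)
err = np.max(np.abs(surv - erlang_survival(p, t)))
print(f"states: {sys.state_labels}")
print(f"sup |chain occupancy - Erlang survival| = {err:.2e}")

# 2. Erlang-SIR epidemic
sir = sir_erlang(SIRParams(beta=5e-4, gamma=0.25, k=4, N0=1000,
                           initial=(990, 10, 0)))
traj = integrate(sir, horizon=80.0, grid=401)
I = traj.observables["I"]
print(f"peak infectious = {I.max():.1f} at t = {traj.times[I.argmax()]:.1f}")
print(f"final susceptible = {traj.observables['S'][-1]:.1f}")
```

Output:

```
states: ['X1', 'X2', 'X3', 'X4', 'Y']
sup |chain occupancy - Erlang survival| = 1.36e-11
peak infectious = 249.0 at t = 12.8
final susceptible = 199.8
```

The first block builds the 4-state chain for an Erlang(0.5, 4) dwell time
and confirms that, with a unit impulse in X₁, the summed occupancy tracks
the Erlang survival function to solver precision.  The second replaces
the classic SIR's exponential infectious period with an Erlang of the
same mean (4 days here, 1/γ) but half the coefficient of variation,
and integrates the epidemic: the narrower infectious-period distribution
gives a sharper, earlier peak than the k = 1 model would.

A CLI session over the same ground:

```sh
glct survival examples/chain.yaml --out survival.csv
glct ensemble examples/chain.yaml --n 20000 --seed 7 --out occupancy.csv
```

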