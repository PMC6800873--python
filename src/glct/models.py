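"""Ready-made epidemiological models and random model fixtures.

The SIR constructors replace the implicit exponential infectious-period
assumption of the classic model with an Erlang or general phase-type
distribution; the chain-trick sub-states I_1..I_k together make up the
infectious compartment, and the force of infection acts on their sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .builders import GLCTModel, ODESystem, RecipientSpec
from .distributions import RateFunction, ValidationError
from .phasetype import PhaseTypeRep


@dataclass(frozen=True)
class SIRParams:
    """Parameters of the Erlang-SIR model.

    beta   — transmission coefficient (per individual per unit time);
    gamma  — recovery rate (1/gamma is the mean infectious period);
    k      — Erlang shape of the infectious period (k = 1 is classic SIR);
    N0     — total population; initial = (S0, I0, R0), summing to N0.
    """

    beta: float
    gamma: float
    k: int
    N0: float
    initial: tuple[float, float, float]

    def __post_init__(self):
        if self.beta < 0 or not (self.gamma > 0):
            raise ValidationError("beta must be >= 0 and gamma > 0")
        if int(self.k) != self.k or self.k < 1:
            raise ValidationError("Erlang shape k must be an integer >= 1")
        if abs(sum(self.initial) - self.N0) > 1e-9 * max(1.0, self.N0):
            raise ValidationError("S0 + I0 + R0 must equal N0")


def sir_erlang(p: SIRParams, frequency_dependent: bool = False) -> ODESystem:
    """SIR with an Erlang(gamma*k, k) infectious period.

    States: S, I_1..I_k, R.  The chain rate is gamma*k so the mean
    infectious period stays 1/gamma while the coefficient of variation
    drops to 1/sqrt(k).  The force of infection is mass-action
    lambda(t) = beta * I(t); set ``frequency_dependent=True`` for the
    beta * I / N0 variant (an extension beyond the mass-action default).
    """
    k = int(p.k)
    r = p.gamma * k
    labels = ["S"] + [f"I{j+1}" for j in range(k)] + ["R"]
    dim = k + 2
    scale = p.N0 if frequency_dependent else 1.0

    def flow(t, x):
        S = x[0]
        I = x[1:k + 1]
        lam = p.beta * I.sum() / scale
        dx = np.empty(dim)
        dx[0] = -lam * S
        dx[1] = lam * S - r * I[0]
        for j in range(1, k):
            dx[1 + j] = r * I[j - 1] - r * I[j]
        dx[k + 1] = r * I[k - 1]
        return dx

    observables = {
        "S": _unit(dim, 0),
        "I": _block(dim, 1, k + 1),
        "R": _unit(dim, k + 1),
        "X_total": _block(dim, 1, k + 1),   # infectious chain occupancy
        "total": np.ones(dim),
    }
    initial = np.zeros(dim)
    initial[0], initial[1], initial[k + 1] = p.initial
    entry = np.zeros(dim)
    entry[1] = 1.0
    return ODESystem(
        state_labels=labels,
        inflow=lambda t: np.zeros(dim),
        flow=flow,
        initial=initial,
        observables=observables,
        entry_weights=entry,
        exit_flow=lambda t, x: r * x[k],
        terms=[{"from": "S", "to": "I1", "expr": "beta*I*S"},
               {"from": f"I{k}", "to": "R", "expr": "gamma*k*Ik"}],
    )


def sir_phase_type(beta: float, alpha, A, N0: float, initial,
                   frequency_dependent: bool = False) -> ODESystem:
    """SIR with a phase-type infectious period (alpha, A).

    dS/dt = -beta I S;  dx/dt = alpha beta I S + A^T x;  I = sum(x);
    R = N0 - S - I tracked explicitly for convenience.
    """
    rep = PhaseTypeRep(initial=np.asarray(alpha, float),
                       subgenerator=np.asarray(A, float))
    n = rep.n
    alpha = rep.initial
    A = rep.subgenerator
    exit_rate = -A.sum(axis=1)
    labels = ["S"] + [f"I{j+1}" for j in range(n)] + ["R"]
    dim = n + 2
    S0, I0, R0 = initial
    if abs(S0 + I0 + R0 - N0) > 1e-9 * max(1.0, N0):
        raise ValidationError("S0 + I0 + R0 must equal N0")
    scale = N0 if frequency_dependent else 1.0

    def flow(t, x):
        S = x[0]
        xi = x[1:n + 1]
        I = xi.sum()
        lam = beta * I / scale
        dx = np.empty(dim)
        dx[0] = -lam * S
        dx[1:n + 1] = alpha * lam * S + A.T @ xi
        dx[n + 1] = exit_rate @ xi
        return dx

    observables = {
        "S": _unit(dim, 0),
        "I": _block(dim, 1, n + 1),
        "R": _unit(dim, n + 1),
        "X_total": _block(dim, 1, n + 1),
        "total": np.ones(dim),
    }
    init = np.zeros(dim)
    init[0] = S0
    init[1:n + 1] = alpha * I0
    init[n + 1] = R0
    entry = np.zeros(dim)
    entry[1:n + 1] = alpha
    return ODESystem(
        state_labels=labels,
        inflow=lambda t: np.zeros(dim),
        flow=flow,
        initial=init,
        observables=observables,
        entry_weights=entry,
        exit_flow=lambda t, x: float(exit_rate @ x[1:n + 1]),
        terms=[{"from": "S", "to": "I", "expr": "alpha*beta*I*S"},
               {"from": "I", "to": "R", "expr": "(-A 1)^T x"}],
    )


def _unit(dim, i):
    w = np.zeros(dim)
    w[i] = 1.0
    return w


def _block(dim, a, b):
    w = np.zeros(dim)
    w[a:b] = 1.0
    return w


# --------------------------------------------------------------------------
# random model fixtures
# --------------------------------------------------------------------------

def fixture_random_glct(n: int, m: int, seed: int,
                        time_varying: bool = False) -> GLCTModel:
    """A random but always-valid general chain-trick model.

    Rates are log-uniform in [0.1, 10]; routing rows are drawn from a flat
    simplex over the n+m destinations; the entry distribution likewise.
    With ``time_varying`` each rate gets a bounded sinusoidal modulation
    r_i(t) = r_i (1 + 0.5 sin(omega_i t + phi_i)) while the routing stays
    constant.  Deterministic in ``seed``.
    """
    if n < 1 or m < 1:
        raise ValidationError("need n >= 1 sub-states and m >= 1 recipients")
    rng = np.random.default_rng(seed)
    base = 10.0 ** rng.uniform(-1, 1, size=n)
    rows = rng.dirichlet(np.ones(n + m), size=n)
    rho = rng.dirichlet(np.ones(n))
    if time_varying:
        omegas = rng.uniform(0.5, 2.0, size=n)
        phis = rng.uniform(0, 2 * np.pi, size=n)
        rates = [RateFunction.sinusoidal(b, 0.5 * b, w, ph)
                 for b, w, ph in zip(base, omegas, phis)]
    else:
        rates = [RateFunction.constant(b) for b in base]
    recipients = [RecipientSpec.sink(f"Y{j+1}") for j in range(m)]
    return GLCTModel.from_arrays(
        substate_labels=[f"X{i+1}" for i in range(n)],
        inflows=np.zeros(n),
        rates=rates,
        within=rows[:, :n],
        exit=rows[:, n:],
        recipients=recipients,
        entry_weights=rho,
    )
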