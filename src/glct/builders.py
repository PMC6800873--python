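"""Mean-field ODE constructors: the linear chain trick and its generalizations.

Every constructor here turns an individual-level stochastic description —
"particles enter state X, dwell according to distribution T, then move to
recipient states Y" — into an explicit, labeled system of mean-field ODEs.
The unifying form is

    dx/dt = I_X(t) + P_X(t)^T (R(t) o x) - R(t) o x

where ``x`` is the vector of sub-state occupancies, ``R`` the vector of
per-sub-state Poisson intensities, ``P_X``/``P_Y`` the (possibly
time-varying) routing probabilities among sub-states and out to recipient
states, and ``o`` the elementwise product.  Specific dwell-time families
(Erlang, event-time, mixture, competing/minimum, maximum, series,
intermediate sub-states) determine the sub-state topology; each builder
assembles the appropriate :class:`GLCTModel` and hands it to
:func:`build_glct`.

Recipient states whose own dwell time is exponential (possibly with
time-varying rate) or Erlang are appended as additional ODE states; a
recipient with a generic survival function is left out of the ODE system
and evaluated after the fact from the stored influx series
(:func:`evaluate_recipient_integral`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .distributions import (CompetingDist, ErlangParams, EventTimeDist,
                            MaxDist, MixtureDist, RateFunction, SeriesDist,
                            ValidationError)
from . import phasetype as pht

ROW_SUM_TOL = 1e-9  # routing row-sum tolerance, sampled on the time grid


# --------------------------------------------------------------------------
# small adapters
# --------------------------------------------------------------------------

def _as_time_func(v) -> Callable[[float], float]:
    if v is None:
        return lambda t: 0.0
    if callable(v):
        return v
    val = float(v)
    return lambda t, _v=val: _v


def _as_vector_func(v, length: int) -> Callable[[float], np.ndarray]:
    if callable(v):
        return lambda t, _v=v: np.asarray(_v(t), dtype=float)
    arr = np.asarray(v, dtype=float)
    if arr.shape != (length,):
        raise ValidationError(f"expected vector of length {length}, "
                              f"got shape {arr.shape}")
    return lambda t, _a=arr: _a


def _as_matrix_func(v, shape) -> Callable[[float], np.ndarray]:
    if callable(v):
        return lambda t, _v=v: np.asarray(_v(t), dtype=float)
    arr = np.asarray(v, dtype=float)
    if arr.shape != tuple(shape):
        raise ValidationError(f"expected matrix of shape {tuple(shape)}, "
                              f"got {arr.shape}")
    return lambda t, _a=arr: _a


def rate_sum(rates: Sequence[RateFunction]) -> RateFunction:
    """The rate function of the superposed process, r(t) = sum_i r_i(t)."""
    rates = list(rates)
    if all(r.is_constant for r in rates):
        return RateFunction.constant(sum(r.value for r in rates))
    return RateFunction(
        evaluate=lambda t: sum(r.evaluate(t) for r in rates),
        cumulative=lambda tau, t: sum(r.cumulative(tau, t) for r in rates),
        bound_on=lambda tau, t: sum(r.bound_on(tau, t) for r in rates),
    )


# --------------------------------------------------------------------------
# recipient specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RecipientSpec:
    """A recipient state Y with its own dwell-time assumption.

    ``dwell`` is one of

    * ``("exp", RateFunction)`` — leave Y at per-capita rate mu(t)
      (first-event time); rate 0 makes Y absorbing;
    * ``("erlang", ErlangParams)`` — Erlang(mu, kappa) dwell, expanded
      into a kappa-state chain;
    * ``("generic", S)`` — arbitrary survival function ``S(t, tau)``;
      the state is then evaluated by quadrature, not appended to the ODEs.

    ``external_inflow`` is the inflow into Y from non-X sources.
    """

    label: str
    dwell: tuple
    external_inflow: Callable[[float], float] | float | None = None

    @staticmethod
    def sink(label: str, external_inflow=None) -> "RecipientSpec":
        """Absorbing recipient (never leaves Y)."""
        return RecipientSpec(label, ("exp", RateFunction.constant(0.0)),
                             external_inflow)

    @staticmethod
    def exponential(label: str, mu, external_inflow=None) -> "RecipientSpec":
        mu = mu if isinstance(mu, RateFunction) else RateFunction.constant(mu)
        return RecipientSpec(label, ("exp", mu), external_inflow)

    @staticmethod
    def erlang(label: str, mu: float, kappa: int,
               external_inflow=None) -> "RecipientSpec":
        return RecipientSpec(label, ("erlang", ErlangParams(mu, kappa)),
                             external_inflow)

    @staticmethod
    def generic(label: str, survival: Callable[[float, float], float],
                external_inflow=None) -> "RecipientSpec":
        return RecipientSpec(label, ("generic", survival), external_inflow)

    @property
    def in_ode(self) -> bool:
        return self.dwell[0] in ("exp", "erlang")


# --------------------------------------------------------------------------
# the general model and the resulting ODE system
# --------------------------------------------------------------------------

@dataclass
class GLCTModel:
    """Sub-state level stochastic assumptions for a focal state X.

    Fields mirror the general construction: per-sub-state inflows
    ``I_X(t)``, per-sub-state first-event rates ``R`` (a list of
    :class:`RateFunction` so the stochastic simulator can bound them),
    routing matrices ``P_X(t)`` (n x n) and ``P_Y(t)`` (n x m), recipient
    specifications, and the entry distribution ``rho`` used when mass is
    injected as an impulse.
    """

    substate_labels: list[str]
    inflows: Callable[[float], np.ndarray]
    rates: list[RateFunction]
    within_routing: Callable[[float], np.ndarray]
    exit_routing: Callable[[float], np.ndarray]
    recipients: list[RecipientSpec] = field(default_factory=list)
    entry_weights: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.substate_labels)
        if len(self.rates) != n:
            raise ValidationError("one rate function per sub-state required")
        if self.entry_weights is None:
            w = np.zeros(n)
            w[0] = 1.0
            self.entry_weights = w
        else:
            self.entry_weights = np.asarray(self.entry_weights, dtype=float)
            if abs(self.entry_weights.sum() - 1.0) > 1e-9:
                raise ValidationError("entry weights must sum to 1")

    @property
    def n(self) -> int:
        return len(self.substate_labels)

    @property
    def m(self) -> int:
        return len(self.recipients)

    @staticmethod
    def from_arrays(substate_labels, inflows, rates, within, exit,
                    recipients=(), entry_weights=None) -> "GLCTModel":
        """Convenience constructor accepting constants or callables."""
        n = len(substate_labels)
        m = len(recipients)
        rates = [r if isinstance(r, RateFunction) else RateFunction.constant(r)
                 for r in rates]
        return GLCTModel(
            substate_labels=list(substate_labels),
            inflows=_as_vector_func(inflows, n),
            rates=rates,
            within_routing=_as_matrix_func(within, (n, n)),
            exit_routing=_as_matrix_func(exit, (n, m)),
            recipients=list(recipients),
            entry_weights=entry_weights,
        )

    def rate_vector(self, t: float) -> np.ndarray:
        return np.array([r.evaluate(t) for r in self.rates])

    def validate_at(self, times: Sequence[float]) -> list[str]:
        """Check routing row sums and rate nonnegativity on a time sample."""
        errs = []
        for t in times:
            px = self.within_routing(t)
            py = self.exit_routing(t)
            full = np.hstack([px, py]) if self.m else px
            if np.any(full < -ROW_SUM_TOL) or np.any(full > 1 + ROW_SUM_TOL):
                errs.append(f"routing entries outside [0,1] at t={t}")
            rows = full.sum(axis=1)
            bad = np.nonzero(np.abs(rows - 1.0) > ROW_SUM_TOL)[0]
            for i in bad:
                errs.append(f"routing row {i} sums to {rows[i]!r} at t={t}")
            rv = self.rate_vector(t)
            if np.any(rv < 0):
                errs.append(f"negative rate at t={t}")
        return errs


@dataclass
class ODESystem:
    """A labeled mean-field ODE system.

    ``rhs(t, x) = inflow(t) + flow(t, x)`` — the split lets callers switch
    external inflow off (impulse-response experiments) without rebuilding.
    ``observables`` maps a name to a weight vector over states;
    ``entry_weights`` places a unit impulse according to the model's entry
    distribution; ``exit_flow`` is the total flux out of X into recipient
    states; ``recipient_influx`` gives the per-recipient influx as a
    function of ``(t, x)`` for post-hoc quadrature evaluation.
    """

    state_labels: list[str]
    inflow: Callable[[float], np.ndarray]
    flow: Callable[[float, np.ndarray], np.ndarray]
    initial: np.ndarray
    observables: dict[str, np.ndarray]
    entry_weights: np.ndarray
    exit_flow: Callable[[float, np.ndarray], float] | None = None
    recipient_influx: dict[str, Callable] = field(default_factory=dict)
    generic_recipients: list[RecipientSpec] = field(default_factory=list)
    terms: list[dict] = field(default_factory=list)
    model: GLCTModel | None = None

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        return self.inflow(t) + self.flow(t, x)

    @property
    def dim(self) -> int:
        return len(self.state_labels)

    def observable(self, name: str, states: np.ndarray) -> np.ndarray:
        w = self.observables[name]
        return np.asarray(states) @ w

    def structure(self) -> dict:
        """JSON-serializable description: states and labeled flow terms."""
        return {"states": list(self.state_labels),
                "terms": [dict(term) for term in self.terms]}


# --------------------------------------------------------------------------
# the generalized chain-trick construction
# --------------------------------------------------------------------------

def build_glct(model: GLCTModel,
               validate_times: Sequence[float] = (0.0,)) -> ODESystem:
    """Expand a :class:`GLCTModel` into explicit mean-field ODEs.

    The X block follows ``dx = I_X + P_X^T (R o x) - R o x``; recipients
    with exponential or Erlang dwell are appended as further ODE states
    receiving influx ``(P_Y^T (R o x))_l``; recipients with a generic
    survival function are exposed through ``recipient_influx`` only.
    """
    errs = model.validate_at(validate_times)
    if errs:
        raise ValidationError("; ".join(errs))

    n, m = model.n, model.m
    labels = list(model.substate_labels)
    ode_recipients: list[tuple[int, RecipientSpec, slice]] = []
    generic: list[RecipientSpec] = []
    pos = n
    for ell, rec in enumerate(model.recipients):
        if rec.dwell[0] == "exp":
            labels.append(rec.label)
            ode_recipients.append((ell, rec, slice(pos, pos + 1)))
            pos += 1
        elif rec.dwell[0] == "erlang":
            kappa = rec.dwell[1].shape
            labels.extend(f"{rec.label}_{j+1}" for j in range(kappa))
            ode_recipients.append((ell, rec, slice(pos, pos + kappa)))
            pos += kappa
        else:
            generic.append(rec)
    dim = pos

    rec_inflows = [(sl, _as_time_func(rec.external_inflow))
                   for _, rec, sl in ode_recipients]

    def inflow(t: float) -> np.ndarray:
        out = np.zeros(dim)
        out[:n] = model.inflows(t)
        for sl, f in rec_inflows:
            out[sl.start] += f(t)
        return out

    def flow(t: float, x: np.ndarray) -> np.ndarray:
        out = np.zeros(dim)
        r = model.rate_vector(t)
        f = r * x[:n]
        px = model.within_routing(t)
        out[:n] = px.T @ f - f
        if m:
            py = model.exit_routing(t)
            influx = py.T @ f
        for ell, rec, sl in ode_recipients:
            kind = rec.dwell[1]
            if rec.dwell[0] == "exp":
                mu = kind.evaluate(t)
                out[sl.start] += influx[ell] - mu * x[sl.start]
            else:  # erlang chain
                mu, kappa = kind.rate, kind.shape
                y = x[sl]
                dy = np.empty(kappa)
                dy[0] = influx[ell] - mu * y[0]
                if kappa > 1:
                    dy[1:] = mu * y[:-1] - mu * y[1:]
                out[sl] += dy
        return out

    def exit_flow(t: float, x: np.ndarray) -> float:
        if m == 0:
            return 0.0
        r = model.rate_vector(t)
        py = model.exit_routing(t)
        return float(np.sum(py.T @ (r * x[:n])))

    recipient_influx = {}
    for ell, rec in enumerate(model.recipients):
        def _influx(t, x, _ell=ell):
            r = model.rate_vector(t)
            py = model.exit_routing(t)
            return float((py.T @ (r * x[:n]))[_ell])
        recipient_influx[rec.label] = _influx

    observables = {"X_total": np.concatenate([np.ones(n), np.zeros(dim - n)])}
    for ell, rec, sl in ode_recipients:
        w = np.zeros(dim)
        w[sl] = 1.0
        observables[rec.label] = w
    observables["total"] = np.ones(dim)

    entry = np.zeros(dim)
    entry[:n] = model.entry_weights

    terms = _structure_terms(model, labels)

    return ODESystem(
        state_labels=labels,
        inflow=inflow,
        flow=flow,
        initial=np.zeros(dim),
        observables=observables,
        entry_weights=entry,
        exit_flow=exit_flow,
        recipient_influx=recipient_influx,
        generic_recipients=generic,
        terms=terms,
        model=model,
    )


def _structure_terms(model: GLCTModel, labels: list[str]) -> list[dict]:
    """Sparsity pattern of the flows at t = 0, as labeled terms."""
    t0 = 0.0
    px = model.within_routing(t0)
    py = model.exit_routing(t0) if model.m else np.zeros((model.n, 0))
    terms = []
    for i in range(model.n):
        terms.append({"from": model.substate_labels[i], "to": None,
                      "expr": f"R[{i}]*x[{i}]"})
        for j in range(model.n):
            if px[i, j] != 0:
                terms.append({"from": model.substate_labels[i],
                              "to": model.substate_labels[j],
                              "expr": f"P_X[{i},{j}]*R[{i}]*x[{i}]"})
        for ell in range(model.m):
            if py[i, ell] != 0:
                terms.append({"from": model.substate_labels[i],
                              "to": model.recipients[ell].label,
                              "expr": f"P_Y[{i},{ell}]*R[{i}]*x[{i}]"})
    return terms


def glct_from_phasetype(rep: "pht.PhaseTypeRep", inflow=0.0,
                        recipients: Sequence[RecipientSpec] = (),
                        labels: list[str] | None = None) -> GLCTModel:
    """GLCT model whose dwell time is the given phase-type distribution.

    The sub-state rates and routing come from the embedded jump process of
    the defining Markov chain, so ``build_glct`` on the result has RHS
    ``I(t) + G_X^T x`` on the X block.
    """
    jump = pht.from_generator(rep)
    n, m = jump.n, jump.m
    if labels is None:
        labels = [f"X{i+1}" for i in range(n)]
    recipients = list(recipients)
    if not recipients:
        recipients = [RecipientSpec.sink(f"Y{j+1}") for j in range(m)]
    if len(recipients) != m:
        raise ValidationError(
            f"phase-type rep routes to {m} absorbing states, got "
            f"{len(recipients)} recipient specs")
    inflow_f = _as_time_func(inflow)
    rho = rep.initial

    def inflows(t):
        return rho * inflow_f(t)

    # absorbing-like states (lambda = 0) keep a formal self-loop-free row;
    # give them a unit exit row so routing rows still sum to one.
    probs = jump.jump_probs.copy()
    for i in range(n):
        if jump.jump_rates[i] == 0 and probs[i].sum() == 0:
            probs[i, -1] = 1.0

    return GLCTModel.from_arrays(
        substate_labels=labels,
        inflows=inflows,
        rates=[RateFunction.constant(l) for l in jump.jump_rates],
        within=probs[:, :n],
        exit=probs[:, n:],
        recipients=recipients,
        entry_weights=rho,
    )


# --------------------------------------------------------------------------
# chain builders
# --------------------------------------------------------------------------

def _default_recipients(recipient) -> list[RecipientSpec]:
    if recipient is None:
        return [RecipientSpec.sink("Y")]
    if isinstance(recipient, RecipientSpec):
        return [recipient]
    return list(recipient)


def build_extended_chain(d: EventTimeDist, inflow=0.0,
                         recipient: RecipientSpec | None = None) -> ODESystem:
    """Chain of k sub-states with common (possibly time-varying) rate r(t).

    With a unit impulse in the first sub-state and zero inflow, the total
    occupancy of the chain equals the k-th event-time survival function.
    """
    return build_proportional_outputs(d, inflow, [1.0],
                                      _default_recipients(recipient))


def build_lct_chain(p: ErlangParams, inflow=0.0,
                    recipient: RecipientSpec | None = None) -> ODESystem:
    """The classic linear chain trick for an Erlang(r, k) dwell time."""
    return build_extended_chain(p.to_event_time(), inflow, recipient)


def build_proportional_outputs(d: EventTimeDist, inflow,
                               probs, recipients) -> ODESystem:
    """Single chain; exits split across recipients with probabilities p_l(t)."""
    recipients = list(recipients)
    k = d.event_index
    m = len(recipients)
    probs_f = _as_vector_func(probs, m)
    labels = [f"X{j+1}" for j in range(k)]
    within = np.zeros((k, k))
    for j in range(k - 1):
        within[j, j + 1] = 1.0

    def exit_routing(t):
        py = np.zeros((k, m))
        py[k - 1] = probs_f(t)
        return py

    model = GLCTModel.from_arrays(
        substate_labels=labels,
        inflows=lambda t, _f=_as_time_func(inflow): _unit_first(k, _f(t)),
        rates=[d.rate] * k,
        within=within,
        exit=exit_routing,
        recipients=recipients,
    )
    return build_glct(model)


def _unit_first(k: int, value: float) -> np.ndarray:
    out = np.zeros(k)
    out[0] = value
    return out


def build_mixture(mix: MixtureDist, inflow, routing, recipients) -> ODESystem:
    """Parallel chains: chain i fed by rho_i(t) I_X(t), length k_i, rate r_i."""
    recipients = list(recipients)
    N = len(mix.components)
    m = len(recipients)
    ks = [c.event_index for c in mix.components]
    n = sum(ks)
    starts = np.concatenate([[0], np.cumsum(ks)])[:-1]
    labels = [f"X{i+1}_{j+1}" for i, k in enumerate(ks) for j in range(k)]
    routing_f = _as_matrix_func(routing, (N, m))
    inflow_f = _as_time_func(inflow)

    within = np.zeros((n, n))
    for i, k in enumerate(ks):
        s = starts[i]
        for j in range(k - 1):
            within[s + j, s + j + 1] = 1.0

    def exit_routing(t):
        py = np.zeros((n, m))
        p = routing_f(t)
        for i, k in enumerate(ks):
            py[starts[i] + k - 1] = p[i]
        return py

    def inflows(t):
        out = np.zeros(n)
        w = mix._weights_at(t)
        out[starts] = w * inflow_f(t)
        return out

    entry = np.zeros(n)
    entry[starts] = mix._weights_at(0.0)

    rates: list[RateFunction] = []
    for c, k in zip(mix.components, ks):
        rates.extend([c.rate] * k)

    model = GLCTModel.from_arrays(
        substate_labels=labels, inflows=inflows, rates=rates,
        within=within, exit=exit_routing, recipients=recipients,
        entry_weights=entry)
    return build_glct(model)


# --------------------------------------------------------------------------
# competing (minimum) dwell times on the event lattice
# --------------------------------------------------------------------------

def _lattice_states(shapes: Sequence[int]) -> list[tuple[int, ...]]:
    """Row-major lexicographic index vectors (first coordinate slowest)."""
    states = [()]
    for k in shapes:
        states = [s + (a,) for s in states for a in range(1, k + 1)]
    return states


def _lattice_label(prefix: str, alpha: tuple) -> str:
    return f"{prefix}_({','.join(str(a) for a in alpha)})"


def build_competing(c: CompetingDist, inflow, routing, recipients,
                    *, label_prefix: str = "X") -> ODESystem:
    """Product-lattice expansion for T = min_i T_i.

    One sub-state per index vector alpha = (a_1..a_n) of awaited event
    numbers; every sub-state loses mass at the summed rate r(t); reaching
    the k_i-th event of process i routes to recipient l with probability
    p_il(t).
    """
    recipients = list(recipients)
    comps = c.components
    nproc = len(comps)
    m = len(recipients)
    shapes = [d.event_index for d in comps]
    states = _lattice_states(shapes)
    index = {a: i for i, a in enumerate(states)}
    n = len(states)
    labels = [_lattice_label(label_prefix, a) for a in states]
    routing_f = _as_matrix_func(routing, (nproc, m))
    total_rate = rate_sum([d.rate for d in comps])

    def _component_rates(t):
        r = np.array([d.rate.evaluate(t) for d in comps])
        tot = r.sum()
        if tot > 0:
            frac = r / tot
        else:
            frac = np.full(nproc, 1.0 / nproc)  # zero flow; split irrelevant
        return r, frac

    def within_routing(t):
        _, frac = _component_rates(t)
        px = np.zeros((n, n))
        for a, i in index.items():
            for comp in range(nproc):
                if a[comp] < shapes[comp]:
                    b = list(a)
                    b[comp] += 1
                    px[i, index[tuple(b)]] += frac[comp]
        return px

    def exit_routing(t):
        _, frac = _component_rates(t)
        p = routing_f(t)
        py = np.zeros((n, m))
        for a, i in index.items():
            for comp in range(nproc):
                if a[comp] == shapes[comp]:
                    py[i] += frac[comp] * p[comp]
        return py

    model = GLCTModel.from_arrays(
        substate_labels=labels,
        inflows=lambda t, _f=_as_time_func(inflow): _unit_first(n, _f(t)),
        rates=[total_rate] * n,
        within=within_routing,
        exit=exit_routing,
        recipients=recipients,
    )
    return build_glct(model)


# --------------------------------------------------------------------------
# intermediate sub-states: reset vs preserve
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IntermediateSpec:
    """Base state with competing exits into intermediate sub-chains.

    ``base`` holds the N+1 competing processes governing the dwell in the
    base sub-state; component 0 is the direct exit out of X.  When
    component i >= 1 wins, the particle moves (within X) to intermediate
    chain j with probability ``inter_routing[i-1, j]``.  Intermediate
    chain j then leads out of X to recipient l with probability
    ``out_routing[j, l]``; a direct (component-0) exit goes to recipient l
    with probability ``exit_probs[l]``.

    ``intermediates`` — list of (rate, kappa) pairs giving each chain's
    Erlang/event-time dwell; used by the clock-resetting construction and
    ignored by the clock-preserving one (there the chains inherit rate r_0
    and depth k_0 from base component 0).
    """

    base: CompetingDist
    inter_routing: object          # N x M_X, constants or callable
    out_routing: object            # M_X x M_Y
    exit_probs: object             # length M_Y
    intermediates: tuple = ()      # [(RateFunction | float, kappa)], reset only
    inflow: object = 0.0
    recipients: tuple = ()


def _norm_intermediates(spec) -> list[tuple[RateFunction, int]]:
    out = []
    for rate, kappa in spec.intermediates:
        rf = rate if isinstance(rate, RateFunction) else RateFunction.constant(rate)
        out.append((rf, int(kappa)))
    return out


def _intermediate_common(spec: IntermediateSpec):
    comps = spec.base.components
    nproc = len(comps)          # N + 1; component 0 = direct exit
    N = nproc - 1
    recipients = _default_recipients(list(spec.recipients) or None)
    my = len(recipients)
    shapes = [d.event_index for d in comps]
    base_states = _lattice_states(shapes)
    return comps, nproc, N, recipients, my, shapes, base_states


def build_intermediate_reset(spec: IntermediateSpec) -> ODESystem:
    """Intermediate transitions that restart the dwell clock.

    The intermediate chains carry their own Erlang/event-time dwell
    (rate varrho_j, shape kappa_j), independent of time already spent in
    the base sub-state, so entering one alters the overall X dwell time.
    """
    comps, nproc, N, recipients, my, shapes, base_states = \
        _intermediate_common(spec)
    inters = _norm_intermediates(spec)
    mx = len(inters)
    index = {a: i for i, a in enumerate(base_states)}
    nb = len(base_states)
    labels = [_lattice_label("X0", a) for a in base_states]
    offsets = []
    pos = nb
    for j, (_, kappa) in enumerate(inters):
        offsets.append(pos)
        labels.extend(f"XI{j+1}_{k+1}" for k in range(kappa))
        pos += kappa
    n = pos

    inter_routing = _as_matrix_func(spec.inter_routing, (N, mx))
    out_routing = _as_matrix_func(spec.out_routing, (mx, my))
    exit_probs = _as_vector_func(spec.exit_probs, my)
    total_rate = rate_sum([d.rate for d in comps])

    rates: list[RateFunction] = [total_rate] * nb
    for rf, kappa in inters:
        rates.extend([rf] * kappa)

    def _frac(t):
        r = np.array([d.rate.evaluate(t) for d in comps])
        tot = r.sum()
        return r / tot if tot > 0 else np.full(nproc, 1.0 / nproc)

    def within_routing(t):
        frac = _frac(t)
        pij = inter_routing(t)
        px = np.zeros((n, n))
        for a, i in index.items():
            for comp in range(nproc):
                if a[comp] < shapes[comp]:
                    b = list(a)
                    b[comp] += 1
                    px[i, index[tuple(b)]] += frac[comp]
                elif comp >= 1:
                    for j in range(mx):
                        px[i, offsets[j]] += frac[comp] * pij[comp - 1, j]
        for j, (_, kappa) in enumerate(inters):
            for k in range(kappa - 1):
                px[offsets[j] + k, offsets[j] + k + 1] = 1.0
        return px

    def exit_routing(t):
        frac = _frac(t)
        p0 = exit_probs(t)
        qjl = out_routing(t)
        py = np.zeros((n, my))
        for a, i in index.items():
            if a[0] == shapes[0]:
                py[i] += frac[0] * p0
        for j, (_, kappa) in enumerate(inters):
            py[offsets[j] + kappa - 1] = qjl[j]
        return py

    model = GLCTModel.from_arrays(
        substate_labels=labels,
        inflows=lambda t, _f=_as_time_func(spec.inflow): _unit_first(n, _f(t)),
        rates=rates,
        within=within_routing,
        exit=exit_routing,
        recipients=recipients,
    )
    return build_glct(model)


def build_intermediate_preserve(spec: IntermediateSpec) -> ODESystem:
    """Intermediate transitions that leave the overall X dwell time unchanged.

    Intermediate chains inherit rate r_0(t) and depth k_0 from the direct
    exit process; a particle leaving a base sub-state with a_0 = j enters
    intermediate slot j, so it still awaits events j..k_0 of process 0.
    The total time in X is then exactly the k_0-th event time of process 0,
    whatever the competing rates and intermediate routing.
    """
    comps, nproc, N, recipients, my, shapes, base_states = \
        _intermediate_common(spec)
    inter_routing_raw = spec.inter_routing
    k0 = shapes[0]
    r0 = comps[0].rate
    mx = np.asarray(inter_routing_raw(0.0) if callable(inter_routing_raw)
                    else inter_routing_raw).shape[1]
    index = {a: i for i, a in enumerate(base_states)}
    nb = len(base_states)
    labels = [_lattice_label("X0", a) for a in base_states]
    offsets = []
    pos = nb
    for j in range(mx):
        offsets.append(pos)
        labels.extend(f"XI{j+1}_{k+1}" for k in range(k0))
        pos += k0
    n = pos

    inter_routing = _as_matrix_func(inter_routing_raw, (N, mx))
    out_routing = _as_matrix_func(spec.out_routing, (mx, my))
    exit_probs = _as_vector_func(spec.exit_probs, my)
    total_rate = rate_sum([d.rate for d in comps])

    rates: list[RateFunction] = [total_rate] * nb + [r0] * (mx * k0)

    def _frac(t):
        r = np.array([d.rate.evaluate(t) for d in comps])
        tot = r.sum()
        return r / tot if tot > 0 else np.full(nproc, 1.0 / nproc)

    def within_routing(t):
        frac = _frac(t)
        pij = inter_routing(t)
        px = np.zeros((n, n))
        for a, i in index.items():
            for comp in range(nproc):
                if a[comp] < shapes[comp]:
                    b = list(a)
                    b[comp] += 1
                    px[i, index[tuple(b)]] += frac[comp]
                elif comp >= 1:
                    slot = a[0]  # events already awaited under process 0
                    for j in range(mx):
                        px[i, offsets[j] + slot - 1] += \
                            frac[comp] * pij[comp - 1, j]
        for j in range(mx):
            for k in range(k0 - 1):
                px[offsets[j] + k, offsets[j] + k + 1] = 1.0
        return px

    def exit_routing(t):
        frac = _frac(t)
        p0 = exit_probs(t)
        qjl = out_routing(t)
        py = np.zeros((n, my))
        for a, i in index.items():
            if a[0] == shapes[0]:
                py[i] += frac[0] * p0
        for j in range(mx):
            py[offsets[j] + k0 - 1] = qjl[j]
        return py

    model = GLCTModel.from_arrays(
        substate_labels=labels,
        inflows=lambda t, _f=_as_time_func(spec.inflow): _unit_first(n, _f(t)),
        rates=rates,
        within=within_routing,
        exit=exit_routing,
        recipients=recipients,
    )
    return build_glct(model)


# --------------------------------------------------------------------------
# series (sum) and maximum dwell times
# --------------------------------------------------------------------------

def build_series(components: Sequence[EventTimeDist], inflow=0.0,
                 exit_probs=None, recipients=None) -> ODESystem:
    """One concatenated chain realizing the sum of independent event times.

    Blockwise rates (first k_1 states carry r_1(t), next k_2 carry r_2(t),
    ...), strict-shift routing, exit only from the last state.  The
    constant-rate, all-k_i = 1 case is the hypoexponential dwell time.
    """
    components = list(components)
    if not components:
        raise ValidationError("series dwell time needs >= 1 component")
    recipients = _default_recipients(recipients)
    m = len(recipients)
    if exit_probs is None:
        exit_probs = np.ones(1) if m == 1 else None
        if exit_probs is None:
            raise ValidationError("exit_probs required for several recipients")
    exit_f = _as_vector_func(exit_probs, m)
    ks = [c.event_index for c in components]
    n = sum(ks)
    labels = [f"X{j+1}" for j in range(n)]
    rates: list[RateFunction] = []
    for c, k in zip(components, ks):
        rates.extend([c.rate] * k)
    within = np.zeros((n, n))
    for j in range(n - 1):
        within[j, j + 1] = 1.0

    def exit_routing(t):
        py = np.zeros((n, m))
        py[n - 1] = exit_f(t)
        return py

    model = GLCTModel.from_arrays(
        substate_labels=labels,
        inflows=lambda t, _f=_as_time_func(inflow): _unit_first(n, _f(t)),
        rates=rates, within=within, exit=exit_routing,
        recipients=recipients)
    return build_glct(model)


def build_max(components: Sequence[ErlangParams], inflow=0.0,
              recipient: RecipientSpec | None = None) -> ODESystem:
    """Lattice-with-absorbed-marks expansion for T = max_i T_i.

    Requires constant rates.  Sub-states are index vectors whose i-th
    coordinate is the awaited event number under process i or the mark '*'
    once that component's clock has finished; a state's exit rate is the
    sum of its unfinished components' rates.  For two Erlang(., 2)
    components this yields exactly 8 transient sub-states.
    """
    d = MaxDist(tuple(components))
    rep = pht._ph_max(d)
    shapes = [c.shape for c in d.components]
    labels = [_lattice_label("X", a) for a in pht._marked_lattice(shapes)]
    recipients = _default_recipients(recipient)
    model = glct_from_phasetype(rep, inflow=inflow, recipients=recipients,
                                labels=labels)
    return build_glct(model)


# --------------------------------------------------------------------------
# generic-survival recipients, evaluated post hoc
# --------------------------------------------------------------------------

def recipient_survival(rec: RecipientSpec) -> Callable[[float, float], float]:
    """The survival function S_Y(t, tau) implied by a recipient spec."""
    kind, param = rec.dwell
    if kind == "exp":
        return lambda t, tau: float(np.exp(-param.cumulative(tau, t)))
    if kind == "erlang":
        from .distributions import erlang_survival
        return lambda t, tau: float(erlang_survival(param, max(t - tau, 0.0)))
    return param


def evaluate_recipient_integral(y_spec: RecipientSpec,
                                influx_times: np.ndarray,
                                influx_values: np.ndarray,
                                t_grid: np.ndarray,
                                y0: float = 0.0) -> np.ndarray:
    """Quadrature evaluation of a recipient state's occupancy.

        y(t) = y(0) S_Y(t, 0) + int_0^t (I_Y(tau) + influx(tau)) S_Y(t, tau) dtau

    ``influx_values`` is the recorded flux from X into Y on
    ``influx_times``; the integral is evaluated by the trapezoid rule on
    that grid, so its accuracy is controlled by the grid spacing.  Every
    requested time must lie inside the recorded history.
    """
    influx_times = np.asarray(influx_times, float)
    influx_values = np.asarray(influx_values, float)
    t_grid = np.asarray(t_grid, float)
    if t_grid.min() < influx_times[0] - 1e-12 or \
            t_grid.max() > influx_times[-1] + 1e-12:
        raise ValueError("requested times outside the recorded influx history")
    surv = recipient_survival(y_spec)
    ext = _as_time_func(y_spec.external_inflow)
    total_in = influx_values + np.array([ext(t) for t in influx_times])
    out = np.empty(len(t_grid))
    for i, t in enumerate(t_grid):
        mask = influx_times <= t + 1e-12
        ts = influx_times[mask]
        if len(ts) == 0 or ts[-1] < t - 1e-12:
            ts = np.append(ts, t)
            vals_in = np.append(total_in[mask],
                                np.interp(t, influx_times, total_in))
        else:
            vals_in = total_in[mask]
        sv = np.array([surv(t, tau) for tau in ts])
        integrand = vals_in * sv
        out[i] = y0 * surv(t, 0.0) + float(np.trapezoid(integrand, ts))
    return out
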