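"""Phase-type distributions: CTMC parameterizations and evaluators.

A phase-type distribution is the absorption (hitting) time of a finite
continuous-time Markov chain started in transient states X = {1..n} with
initial distribution rho, absorbing states Y = {1..m}.  Three equivalent
parameterizations are supported:

* :class:`RateRoutingRep` — per-state Poisson rates r_i and a routing
  matrix [P_X | P_Y] whose rows sum to one (self-loops allowed);
* :class:`JumpRep` — the embedded jump process: thinned rates
  lambda_i = r_i (1 - p_ii) and self-loop-free routing probabilities;
* :class:`PhaseTypeRep` — the generator form (rho, G_X, G_Y) with
  density f(t) = rho^T e^(t G_X) (-G_X 1) and CDF F(t) = 1 - rho^T e^(t G_X) 1.

The m x m identity block of the full transition matrix (absorbing states)
is implicit and never stored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .distributions import (CompetingDist, DwellSpec, ErlangParams,
                            EventTimeDist, MaxDist, MixtureDist, SeriesDist,
                            ValidationError)

_TOL = 1e-12  # row-sum / stochasticity validation tolerance


# --------------------------------------------------------------------------
# representations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RateRoutingRep:
    """(rho, R, P) parameterization: rates plus a row-stochastic routing."""

    initial: np.ndarray         # length n, sums to 1
    rates: np.ndarray           # length n, > 0
    within: np.ndarray          # n x n, routing among transient states
    exit: np.ndarray            # n x m, routing to absorbing states

    def __post_init__(self):
        object.__setattr__(self, "initial", np.asarray(self.initial, float))
        object.__setattr__(self, "rates", np.asarray(self.rates, float))
        object.__setattr__(self, "within", np.asarray(self.within, float))
        object.__setattr__(self, "exit", np.asarray(self.exit, float))
        errs = validate(self)
        if errs:
            raise ValidationError("; ".join(errs))

    @property
    def n(self) -> int:
        return len(self.rates)

    @property
    def m(self) -> int:
        return self.exit.shape[1]


@dataclass(frozen=True)
class JumpRep:
    """Embedded jump process: thinned rates and self-loop-free routing."""

    initial: np.ndarray         # length n
    jump_rates: np.ndarray      # length n, >= 0 (0 only if absorbing-like)
    jump_probs: np.ndarray      # n x (n+m), zero diagonal on first n columns

    def __post_init__(self):
        object.__setattr__(self, "initial", np.asarray(self.initial, float))
        object.__setattr__(self, "jump_rates",
                           np.asarray(self.jump_rates, float))
        object.__setattr__(self, "jump_probs",
                           np.asarray(self.jump_probs, float))
        errs = validate(self)
        if errs:
            raise ValidationError("; ".join(errs))

    @property
    def n(self) -> int:
        return len(self.jump_rates)

    @property
    def m(self) -> int:
        return self.jump_probs.shape[1] - self.n


@dataclass(frozen=True)
class PhaseTypeRep:
    """Generator parameterization (rho, G_X, G_Y).

    ``subgenerator`` has nonpositive diagonal, nonnegative off-diagonal and
    row sums <= 0; together with the optional ``exit_block`` the rows of
    [G_X | G_Y] sum to zero.
    """

    initial: np.ndarray                 # rho, length n
    subgenerator: np.ndarray            # G_X, n x n
    exit_block: np.ndarray | None = None  # G_Y, n x m

    def __post_init__(self):
        object.__setattr__(self, "initial", np.asarray(self.initial, float))
        object.__setattr__(self, "subgenerator",
                           np.asarray(self.subgenerator, float))
        if self.exit_block is None:
            gy = -self.subgenerator.sum(axis=1, keepdims=True)
            gy[np.abs(gy) < _TOL] = 0.0
            object.__setattr__(self, "exit_block", gy)
        else:
            object.__setattr__(self, "exit_block",
                               np.asarray(self.exit_block, float))
        errs = validate(self)
        if errs:
            raise ValidationError("; ".join(errs))

    @property
    def n(self) -> int:
        return len(self.initial)

    @property
    def m(self) -> int:
        return self.exit_block.shape[1]


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def validate(rep) -> list[str]:
    """Check the invariants of any representation; return violations.

    Each message names the failed invariant and the offending index.
    An empty list means the representation is valid at tolerance 1e-12.
    Specs failing validation are rejected, never repaired.
    """
    errs: list[str] = []

    def check_initial(rho):
        if np.any(rho < -_TOL):
            for i in np.nonzero(rho < -_TOL)[0]:
                errs.append(f"initial[{i}] < 0")
        if abs(rho.sum() - 1.0) > 1e-9:
            errs.append(f"initial distribution sums to {rho.sum()!r}, not 1")

    if isinstance(rep, RateRoutingRep):
        check_initial(rep.initial)
        for i, r in enumerate(rep.rates):
            if not r > 0:
                errs.append(f"rates[{i}] must be > 0, got {r}")
        full = np.hstack([rep.within, rep.exit])
        if np.any(full < -_TOL) or np.any(full > 1 + _TOL):
            errs.append("routing probabilities must lie in [0, 1]")
        rows = full.sum(axis=1)
        for i, s in enumerate(rows):
            if abs(s - 1.0) > _TOL * max(1, full.shape[1]) and abs(s - 1) > 1e-9:
                errs.append(f"routing row {i} sums to {s!r}, not 1")
    elif isinstance(rep, JumpRep):
        check_initial(rep.initial)
        n = rep.n
        if np.any(rep.jump_rates < 0):
            errs.append("jump rates must be >= 0")
        diag = np.diagonal(rep.jump_probs[:, :n])
        for i, d in enumerate(diag):
            if abs(d) > _TOL:
                errs.append(f"jump_probs[{i},{i}] must be 0 (no self-loops)")
        for i in range(n):
            if rep.jump_rates[i] > 0:
                s = rep.jump_probs[i].sum()
                if abs(s - 1.0) > 1e-9:
                    errs.append(f"jump_probs row {i} sums to {s!r}, not 1")
    elif isinstance(rep, PhaseTypeRep):
        check_initial(rep.initial)
        gx, gy = rep.subgenerator, rep.exit_block
        n = gx.shape[0]
        if gx.shape != (n, n):
            errs.append("subgenerator must be square")
        for i in range(n):
            if gx[i, i] > _TOL:
                errs.append(f"subgenerator diagonal [{i},{i}] must be <= 0")
        off = gx - np.diag(np.diagonal(gx))
        if np.any(off < -_TOL):
            i, j = np.argwhere(off < -_TOL)[0]
            errs.append(f"subgenerator off-diagonal [{i},{j}] must be >= 0")
        if np.any(gy < -_TOL):
            i, j = np.argwhere(gy < -_TOL)[0]
            errs.append(f"exit block [{i},{j}] must be >= 0")
        rows = gx.sum(axis=1) + gy.sum(axis=1)
        for i, s in enumerate(rows):
            if abs(s) > 1e-9:
                errs.append(f"generator row {i} sums to {s!r}, not 0")
    else:
        errs.append(f"unknown representation type {type(rep).__name__}")
    return errs


# --------------------------------------------------------------------------
# conversions
# --------------------------------------------------------------------------

def thin(r: RateRoutingRep) -> JumpRep:
    """Thin self-loops: lambda_i = r_i (1 - p_ii), p~_ij = p_ij/(1 - p_ii).

    Thinning the underlying Poisson process removes jumps that return a
    particle instantly to its current state; the result is the embedded
    jump process of the same CTMC.
    """
    n, m = r.n, r.m
    pii = np.diagonal(r.within).copy()
    if np.any(pii >= 1 - _TOL):
        i = int(np.nonzero(pii >= 1 - _TOL)[0][0])
        raise ValidationError(
            f"state {i} has self-loop probability 1: the particle never "
            "leaves, no jump representation exists")
    lam = r.rates * (1.0 - pii)
    probs = np.hstack([r.within, r.exit]) / (1.0 - pii)[:, None]
    probs[np.arange(n), np.arange(n)] = 0.0
    return JumpRep(initial=r.initial, jump_rates=lam, jump_probs=probs)


def jump_to_rate_routing(j: JumpRep) -> RateRoutingRep:
    """The self-loop-free rate/routing view of a jump representation."""
    n = j.n
    return RateRoutingRep(initial=j.initial, rates=j.jump_rates,
                          within=j.jump_probs[:, :n],
                          exit=j.jump_probs[:, n:])


def to_generator(r: RateRoutingRep) -> PhaseTypeRep:
    """Generator form: G_ii = -lambda_i, G_ij = lambda_i p~_ij (j != i)."""
    j = thin(r)
    return jump_to_generator(j)


def jump_to_generator(j: JumpRep) -> PhaseTypeRep:
    n = j.n
    g = j.jump_rates[:, None] * j.jump_probs
    gx = g[:, :n].copy()
    gx[np.arange(n), np.arange(n)] = -j.jump_rates
    return PhaseTypeRep(initial=j.initial, subgenerator=gx,
                        exit_block=g[:, n:])


def from_generator(g: PhaseTypeRep) -> JumpRep:
    """Recover the embedded jump process: lambda_i = -G_ii, p~_ij = G_ij/lambda_i."""
    n, m = g.n, g.m
    lam = -np.diagonal(g.subgenerator)
    full = np.hstack([g.subgenerator, g.exit_block]).astype(float).copy()
    full[np.arange(n), np.arange(n)] = 0.0
    probs = np.zeros_like(full)
    for i in range(n):
        if lam[i] > 0:
            probs[i] = full[i] / lam[i]
        elif np.any(np.abs(full[i]) > _TOL):
            raise ValidationError(
                f"state {i} has zero exit rate but nonzero off-diagonal "
                "generator entries")
    return JumpRep(initial=g.initial, jump_rates=lam, jump_probs=probs)


# --------------------------------------------------------------------------
# density / CDF / moments
# --------------------------------------------------------------------------

def ph_pdf(g: PhaseTypeRep, t) -> np.ndarray | float:
    """f(t) = rho^T e^(t G_X) (-G_X 1)."""
    exit_rate = -g.subgenerator.sum(axis=1)
    scalar = np.isscalar(t)
    ts = np.atleast_1d(np.asarray(t, float))
    if np.any(ts < 0):
        raise ValueError("ph_pdf requires t >= 0")
    out = np.array([float(g.initial @ expm(ti * g.subgenerator) @ exit_rate)
                    for ti in ts])
    return float(out[0]) if scalar else out


def ph_cdf(g: PhaseTypeRep, t) -> np.ndarray | float:
    """F(t) = 1 - rho^T e^(t G_X) 1."""
    ones = np.ones(g.n)
    scalar = np.isscalar(t)
    ts = np.atleast_1d(np.asarray(t, float))
    if np.any(ts < 0):
        raise ValueError("ph_cdf requires t >= 0")
    out = np.array([1.0 - float(g.initial @ expm(ti * g.subgenerator) @ ones)
                    for ti in ts])
    return float(out[0]) if scalar else out


def ph_survival(g: PhaseTypeRep, t):
    return 1.0 - ph_cdf(g, t)


def ph_mean(g: PhaseTypeRep) -> float:
    """Mean absorption time rho^T (-G_X)^(-1) 1."""
    return float(g.initial @ np.linalg.solve(-g.subgenerator, np.ones(g.n)))


# --------------------------------------------------------------------------
# construction from dwell specifications
# --------------------------------------------------------------------------

def _require_constant(rate) -> float:
    if not rate.is_constant:
        raise ValidationError(
            "phase-type representations require constant rates; use the "
            "time-varying ODE builders instead")
    return rate.value


def _erlang_blocks(p: ErlangParams) -> np.ndarray:
    """Subgenerator of the k-state Erlang chain."""
    k, r = p.shape, p.rate
    gx = -r * np.eye(k)
    for i in range(k - 1):
        gx[i, i + 1] = r
    return gx


def ph_from_dwellspec(d: DwellSpec) -> PhaseTypeRep:
    """Phase-type representation of a constant-rate dwell specification.

    Supported variants: Erlang (k-state chain), mixture (block diagonal,
    hyper-Erlang), series (concatenated chains, hypoexponential),
    min/competing (product lattice) and max (lattice with absorbed marks).
    """
    if isinstance(d, PhaseTypeRep):
        return d
    if isinstance(d, ErlangParams):
        gx = _erlang_blocks(d)
        rho = np.zeros(d.shape)
        rho[0] = 1.0
        return PhaseTypeRep(initial=rho, subgenerator=gx)
    if isinstance(d, EventTimeDist):
        r = _require_constant(d.rate)
        return ph_from_dwellspec(ErlangParams(rate=r, shape=d.event_index))
    if isinstance(d, MixtureDist):
        if callable(d.weights):
            raise ValidationError(
                "phase-type mixtures require constant weights")
        blocks, rhos = [], []
        for w, c in zip(d.weights, d.components):
            rep = ph_from_dwellspec(c)
            blocks.append(rep.subgenerator)
            rhos.append(w * rep.initial)
        ntot = sum(b.shape[0] for b in blocks)
        gx = np.zeros((ntot, ntot))
        pos = 0
        for b in blocks:
            k = b.shape[0]
            gx[pos:pos + k, pos:pos + k] = b
            pos += k
        return PhaseTypeRep(initial=np.concatenate(rhos), subgenerator=gx)
    if isinstance(d, SeriesDist):
        rates, shapes = [], []
        for c in d.components:
            rates.append(_require_constant(c.rate))
            shapes.append(c.event_index)
        n = sum(shapes)
        rvec = np.concatenate([np.full(k, r) for r, k in zip(rates, shapes)])
        gx = -np.diag(rvec)
        for i in range(n - 1):
            gx[i, i + 1] = rvec[i]
        rho = np.zeros(n)
        rho[0] = 1.0
        return PhaseTypeRep(initial=rho, subgenerator=gx)
    if isinstance(d, CompetingDist):
        return _ph_min(d)
    if isinstance(d, MaxDist):
        return _ph_max(d)
    raise ValidationError(f"unsupported dwell spec {type(d).__name__}")


def _ph_min(d: CompetingDist) -> PhaseTypeRep:
    """Product-lattice CTMC for the minimum of independent Erlang times.

    One transient state per index vector alpha = (a_1..a_n), a_i in
    {1..k_i}: the event a particle is awaiting under each process.  Every
    state loses mass at the summed rate; reaching any k_i-th event absorbs.
    """
    rates = [_require_constant(c.rate) for c in d.components]
    shapes = [c.event_index for c in d.components]
    states = list(_lattice(shapes))
    index = {a: i for i, a in enumerate(states)}
    n = len(states)
    r_tot = sum(rates)
    gx = np.zeros((n, n))
    for a, i in index.items():
        gx[i, i] = -r_tot
        for comp, (ri, ki) in enumerate(zip(rates, shapes)):
            if a[comp] < ki:
                b = list(a)
                b[comp] += 1
                gx[i, index[tuple(b)]] = ri
    rho = np.zeros(n)
    rho[index[tuple([1] * len(shapes))]] = 1.0
    return PhaseTypeRep(initial=rho, subgenerator=gx)


def _ph_max(d: MaxDist) -> PhaseTypeRep:
    """Lattice-with-absorbed-marks CTMC for the maximum of Erlang times.

    Each coordinate is an awaited event number 1..k_i or the mark '*'
    (that component's Erlang clock has finished).  A state's exit rate is
    the sum of rates of its unfinished components; the all-marked state is
    the absorbing exit.
    """
    rates = [c.rate for c in d.components]
    shapes = [c.shape for c in d.components]
    states = list(_marked_lattice(shapes))
    index = {a: i for i, a in enumerate(states)}
    n = len(states)
    gx = np.zeros((n, n))
    gy = np.zeros((n, 1))
    for a, i in index.items():
        for comp, (ri, ki) in enumerate(zip(rates, shapes)):
            if a[comp] == "*":
                continue
            b = list(a)
            b[comp] = b[comp] + 1 if a[comp] < ki else "*"
            gx[i, i] -= ri
            tb = tuple(b)
            if all(x == "*" for x in tb):
                gy[i, 0] += ri
            else:
                gx[i, index[tb]] += ri
    rho = np.zeros(n)
    rho[index[tuple([1] * len(shapes))]] = 1.0
    return PhaseTypeRep(initial=rho, subgenerator=gx, exit_block=gy)


def _lattice(shapes):
    """Row-major lexicographic index vectors, first coordinate slowest."""
    if not shapes:
        yield ()
        return
    for head in range(1, shapes[0] + 1):
        for tail in _lattice(shapes[1:]):
            yield (head,) + tail


def _marked_lattice(shapes):
    """Lattice coordinates extended by the mark '*', all-marked excluded."""
    def coords(k):
        return list(range(1, k + 1)) + ["*"]

    def rec(sh):
        if not sh:
            yield ()
            return
        for head in coords(sh[0]):
            for tail in rec(sh[1:]):
                yield (head,) + tail

    for a in rec(list(shapes)):
        if not all(x == "*" for x in a):
            yield a


def generator_edge_list(g: PhaseTypeRep,
                        labels: list[str] | None = None) -> list[dict]:
    """Export G as labeled edges for graph inspection / serialization."""
    n, m = g.n, g.m
    if labels is None:
        labels = [f"X{i+1}" for i in range(n)]
    ylabels = [f"Y{j+1}" for j in range(m)]
    edges = []
    for i in range(n):
        for j in range(n):
            if i != j and g.subgenerator[i, j] != 0:
                edges.append({"from": labels[i], "to": labels[j],
                              "rate": float(g.subgenerator[i, j])})
        for j in range(m):
            if g.exit_block[i, j] != 0:
                edges.append({"from": labels[i], "to": ylabels[j],
                              "rate": float(g.exit_block[i, j])})
    return edges
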