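"""Closed-form dwell-time distribution evaluators.

These are the analytic building blocks of the linear chain trick: the
Erlang distribution (the k-th event time of a homogeneous Poisson process
with rate r), its nonhomogeneous generalization (k-th event times under a
Poisson process with time-varying intensity r(t)), and the compound
distributions built from them — finite mixtures, the minimum of independent
event times ("competing" processes), the maximum, and sums in series.

Every evaluator here is an independent oracle for the ODE builders in
:mod:`glct.builders`: with an impulse of mass placed in a freshly built
chain, the total occupancy of the chain must reproduce the survival
function evaluated here.

Notation used throughout:

* ``g_r^k(t)``   — Erlang(r, k) density,
* ``S_r^k(t)``   — Erlang(r, k) survival function = sum_{j<=k} g_r^j(t)/r,
* ``m(t, tau)``  — integrated intensity  int_tau^t r(s) ds,
* ``u_r^k``      — m^{k-1} e^{-m} / (k-1)!  so that the event-time density
  is ``h_r^k = r(t) u_r^k``; the u-form stays well defined when r(t) = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np
from scipy import integrate as _integrate
from scipy.special import gammaln


class ValidationError(ValueError):
    """A model or distribution specification violates its invariants."""


# --------------------------------------------------------------------------
# low-level kernels
# --------------------------------------------------------------------------

def _u_kernel(k: int, m):
    """u^k(m) = m^(k-1) e^(-m) / (k-1)!, elementwise in m, stable for large k.

    This is the paper-agnostic Poisson kernel: P(N = k-1) for N ~ Poisson(m).
    At m == 0 it is 1 for k == 1 and 0 otherwise.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("integrated intensity m must be nonnegative")
    if k == 1:
        return np.exp(-m)
    with np.errstate(divide="ignore"):
        logm = np.where(m > 0, np.log(np.where(m > 0, m, 1.0)), -np.inf)
    logu = (k - 1) * logm - m - gammaln(k)
    return np.where(m > 0, np.exp(logu), 0.0)


def _u_partial_sum(k: int, m):
    """sum_{j=1..k} u^j(m) — the survival function in terms of m."""
    m = np.asarray(m, dtype=float)
    out = np.zeros_like(m)
    for j in range(1, k + 1):
        out = out + _u_kernel(j, m)
    return np.clip(out, 0.0, 1.0)


# --------------------------------------------------------------------------
# rate functions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RateFunction:
    """A nonnegative Poisson process intensity r(t).

    Parameters
    ----------
    evaluate
        Pointwise intensity, ``r(t) >= 0``.
    cumulative
        Integrated intensity ``m(tau, t) = int_tau^t r(s) ds``.  When a
        closed form is not supplied, adaptive quadrature (absolute
        tolerance 1e-10) is used.
    bound_on
        Upper bound of r on ``[tau, t]``, used by the thinning sampler.
        The automatic fallback is 1.5x the max of r on a 1000-point grid
        (a heuristic; supply an exact bound when one is known).
    is_constant, value
        Set when the rate is a known constant, enabling exact shortcuts.
    """

    evaluate: Callable[[float], float]
    cumulative: Callable[[float, float], float]
    bound_on: Callable[[float, float], float]
    is_constant: bool = False
    value: float = float("nan")

    @staticmethod
    def constant(r: float) -> "RateFunction":
        if r < 0:
            raise ValidationError(f"constant rate must be >= 0, got {r}")
        r = float(r)
        return RateFunction(
            evaluate=lambda t, _r=r: _r,
            cumulative=lambda tau, t, _r=r: _r * (t - tau),
            bound_on=lambda tau, t, _r=r: _r,
            is_constant=True,
            value=r,
        )

    @staticmethod
    def sinusoidal(a: float, b: float, omega: float = 1.0,
                   phi: float = 0.0) -> "RateFunction":
        """r(t) = a + b sin(omega t + phi); requires a >= |b| so r >= 0."""
        if a < abs(b):
            raise ValidationError(
                f"sinusoidal rate needs a >= |b| for nonnegativity "
                f"(a={a}, b={b})")

        def ev(t):
            return a + b * math.sin(omega * t + phi)

        def cum(tau, t):
            if omega == 0:
                return (a + b * math.sin(phi)) * (t - tau)
            return a * (t - tau) - (b / omega) * (
                math.cos(omega * t + phi) - math.cos(omega * tau + phi))

        return RateFunction(
            evaluate=ev, cumulative=cum,
            bound_on=lambda tau, t: a + abs(b))

    @staticmethod
    def piecewise_linear(times: Sequence[float],
                         values: Sequence[float]) -> "RateFunction":
        """Linear interpolation through knots, clamped outside the range."""
        ts = np.asarray(times, dtype=float)
        vs = np.asarray(values, dtype=float)
        if ts.ndim != 1 or ts.shape != vs.shape or len(ts) < 2:
            raise ValidationError("piecewise_linear needs matching knot arrays")
        if np.any(np.diff(ts) <= 0):
            raise ValidationError("piecewise_linear knot times must increase")
        if np.any(vs < 0):
            raise ValidationError("piecewise_linear rate values must be >= 0")

        def ev(t):
            return float(np.interp(t, ts, vs))

        def cum(tau, t):
            # exact integral of the interpolant: trapezoid over the knots
            # spanned by [tau, t] plus the two partial end segments.
            if t < tau:
                raise ValueError("cumulative requires t >= tau")
            if t == tau:
                return 0.0
            grid = np.concatenate(([tau], ts[(ts > tau) & (ts < t)], [t]))
            vals = np.interp(grid, ts, vs)
            return float(np.trapezoid(vals, grid))

        def bound(tau, t):
            grid = np.concatenate(([tau], ts[(ts > tau) & (ts < t)], [t]))
            return float(np.max(np.interp(grid, ts, vs)))

        return RateFunction(evaluate=ev, cumulative=cum, bound_on=bound)

    @staticmethod
    def from_callable(f: Callable[[float], float],
                      cumulative: Callable[[float, float], float] | None = None,
                      bound_on: Callable[[float, float], float] | None = None,
                      ) -> "RateFunction":
        """Wrap an arbitrary callable rate.

        Without a closed-form cumulative, ``m(tau, t)`` falls back to
        adaptive quadrature (epsabs 1e-10); without a bound, to 1.5x the
        max of r over a 1000-point sampling grid.
        """
        if cumulative is None:
            def cumulative(tau, t, _f=f):
                if t == tau:
                    return 0.0
                val, _ = _integrate.quad(_f, tau, t, epsabs=1e-10, limit=200)
                return val
        if bound_on is None:
            def bound_on(tau, t, _f=f):
                grid = np.linspace(tau, t, 1000)
                return 1.5 * max(float(_f(s)) for s in grid)
        return RateFunction(evaluate=f, cumulative=cumulative,
                            bound_on=bound_on)


# --------------------------------------------------------------------------
# dwell-time specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ErlangParams:
    """Erlang(rate r, integer shape k) dwell time."""

    rate: float
    shape: int

    def __post_init__(self):
        if not (self.rate > 0):
            raise ValidationError(f"Erlang rate must be > 0, got {self.rate}")
        if int(self.shape) != self.shape or self.shape < 1:
            raise ValidationError(
                f"Erlang shape must be an integer >= 1, got {self.shape}")
        object.__setattr__(self, "shape", int(self.shape))

    def to_event_time(self) -> "EventTimeDist":
        return EventTimeDist(RateFunction.constant(self.rate), self.shape)


@dataclass(frozen=True)
class EventTimeDist:
    """k-th event time under a (possibly nonhomogeneous) Poisson process."""

    rate: RateFunction
    event_index: int

    def __post_init__(self):
        if int(self.event_index) != self.event_index or self.event_index < 1:
            raise ValidationError(
                f"event_index must be an integer >= 1, got {self.event_index}")
        object.__setattr__(self, "event_index", int(self.event_index))

    def density(self, t, tau: float = 0.0):
        return nhpp_event_density(self, t, tau)

    def survival(self, t, tau: float = 0.0):
        return nhpp_event_survival(self, t, tau)


WeightVector = Union[Sequence[float], Callable[[float], Sequence[float]]]


@dataclass(frozen=True)
class MixtureDist:
    """Finite mixture of Poisson-process event-time distributions.

    ``weights`` may be a fixed probability vector or a callable of the
    entry time tau; it must sum to one (tolerance 1e-9) whenever evaluated.
    """

    weights: WeightVector
    components: tuple[EventTimeDist, ...]

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))
        if len(self.components) < 1:
            raise ValidationError("mixture needs at least one component")
        if not callable(self.weights):
            w = self._weights_at(0.0)
            if len(w) != len(self.components):
                raise ValidationError("weights/components length mismatch")

    def _weights_at(self, tau: float) -> np.ndarray:
        w = self.weights(tau) if callable(self.weights) else self.weights
        w = np.asarray(w, dtype=float)
        if np.any(w < 0):
            raise ValidationError("mixture weights must be >= 0")
        if abs(float(w.sum()) - 1.0) > 1e-9:
            raise ValidationError(
                f"mixture weights must sum to 1 at tau={tau}, got {w.sum()}")
        return w

    def survival(self, t, tau: float = 0.0):
        return mixture_survival(self, t, tau)


@dataclass(frozen=True)
class CompetingDist:
    """Minimum of n >= 2 independent Poisson-process event times.

    The dwell time is T = min_i T_i; which component attains the minimum
    typically determines routing out of the state.
    """

    components: tuple[EventTimeDist, ...]

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))
        if len(self.components) < 2:
            raise ValidationError(
                "competing dwell time needs at least 2 components")

    def survival(self, t, tau: float = 0.0):
        return competing_survival(self, t, tau)


@dataclass(frozen=True)
class MaxDist:
    """Maximum of independent Erlang dwell times (constant rates only)."""

    components: tuple[ErlangParams, ...]

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))
        if len(self.components) < 1:
            raise ValidationError("max dwell time needs >= 1 component")

    def survival(self, t, tau: float = 0.0):
        t = np.asarray(t, dtype=float)
        cdf = np.ones_like(t)
        for c in self.components:
            cdf = cdf * (1.0 - erlang_survival(c, t - tau))
        return 1.0 - cdf


@dataclass(frozen=True)
class SeriesDist:
    """Sum of independent event times traversed in series.

    The all-``k_i = 1``, constant-rate case is the hypoexponential
    distribution.  No closed-form survival is exposed here; use the
    phase-type representation (:func:`glct.phasetype.ph_from_dwellspec`)
    or the chain built by :func:`glct.builders.build_series`.
    """

    components: tuple[EventTimeDist, ...]

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))
        if len(self.components) < 1:
            raise ValidationError("series dwell time needs >= 1 component")


# union of dwell-time variants accepted by samplers / converters; the
# phase-type variant (glct.phasetype.PhaseTypeRep) also qualifies.
DwellSpec = Union[ErlangParams, EventTimeDist, MixtureDist, CompetingDist,
                  MaxDist, SeriesDist]


# --------------------------------------------------------------------------
# Erlang evaluators
# --------------------------------------------------------------------------

def erlang_pdf(p: ErlangParams, t):
    """Erlang density g_r^k(t) = r (rt)^(k-1) e^(-rt) / (k-1)!."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("erlang_pdf requires t >= 0")
    return p.rate * _u_kernel(p.shape, p.rate * t)


def erlang_survival(p: ErlangParams, t):
    """Erlang survival S_r^k(t) = sum_{j=1..k} g_r^j(t) / r."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("erlang_survival requires t >= 0")
    return _u_partial_sum(p.shape, p.rate * t)


def erlang_cdf(p: ErlangParams, t):
    return 1.0 - erlang_survival(p, t)


def erlang_moments(p: ErlangParams) -> tuple[float, float, float]:
    """(mean, variance, coefficient of variation) = (k/r, k/r^2, 1/sqrt(k))."""
    k, r = p.shape, p.rate
    return k / r, k / r**2, 1.0 / math.sqrt(k)


def match_erlang_moments(mean: float, variance: float,
                         rounding: str = "nearest") -> ErlangParams:
    """Erlang parameters matching a target mean and (approximately) variance.

    The gamma shape ``mean^2/variance`` is rounded to an integer k >= 1
    (mode ``nearest``, ``floor`` or ``ceil``) and the rate set to
    ``k/mean`` so the mean is preserved exactly; the realized variance
    becomes ``k/r^2 = mean^2/k``.
    """
    if not (mean > 0) or not (variance > 0):
        raise ValueError("mean and variance must be > 0")
    k_real = mean**2 / variance
    if rounding == "nearest":
        k = round(k_real)
    elif rounding == "floor":
        k = math.floor(k_real)
    elif rounding == "ceil":
        k = math.ceil(k_real)
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    k = max(1, int(k))
    return ErlangParams(rate=k / mean, shape=k)


# --------------------------------------------------------------------------
# nonhomogeneous Poisson process event-time evaluators
# --------------------------------------------------------------------------

def nhpp_u(d: EventTimeDist, t: float, tau: float = 0.0) -> float:
    """u_r^k(t, tau) = m^(k-1) e^(-m)/(k-1)! with m = int_tau^t r(s) ds.

    The density is r(t) * u; the u-form remains defined where r(t) = 0.
    """
    if t < tau:
        raise ValueError("nhpp evaluators require t >= tau")
    m = d.rate.cumulative(tau, t)
    return float(_u_kernel(d.event_index, m))


def nhpp_event_density(d: EventTimeDist, t: float, tau: float = 0.0) -> float:
    """h_r^k(t, tau) = r(t) m^(k-1) e^(-m) / (k-1)!."""
    return d.rate.evaluate(t) * nhpp_u(d, t, tau)


def nhpp_event_survival(d: EventTimeDist, t: float, tau: float = 0.0) -> float:
    """S_r^k(t, tau) = sum_{j=1..k} u_r^j(t, tau)."""
    if t < tau:
        raise ValueError("nhpp evaluators require t >= tau")
    m = d.rate.cumulative(tau, t)
    return float(_u_partial_sum(d.event_index, np.asarray(m)))


def mixture_survival(mx: MixtureDist, t: float, tau: float = 0.0) -> float:
    """sum_i rho_i(tau) S_{r_i}^{k_i}(t, tau)."""
    w = mx._weights_at(tau)
    if len(w) != len(mx.components):
        raise ValidationError("weights/components length mismatch")
    return float(sum(wi * nhpp_event_survival(c, t, tau)
                     for wi, c in zip(w, mx.components)))


def mixture_pdf(mx: MixtureDist, t: float, tau: float = 0.0) -> float:
    w = mx._weights_at(tau)
    return float(sum(wi * nhpp_event_density(c, t, tau)
                     for wi, c in zip(w, mx.components)))


def competing_survival(c: CompetingDist, t: float, tau: float = 0.0) -> float:
    """Survival of the minimum: product of the component survivals."""
    out = 1.0
    for comp in c.components:
        out *= nhpp_event_survival(comp, t, tau)
    return out


def conditional_survival(d: EventTimeDist, s: float, t: float) -> float:
    """P(T - s > t | T > s) for a first-event time T started at 0.

    First-event times are memoryless up to a shift of the rate function:
    the conditional survival is exp(-m(t+s, s)).  For a constant rate this
    is the unconditional exponential survival e^(-rt).  Only defined for
    ``event_index == 1``.
    """
    if d.event_index != 1:
        raise ValidationError(
            "conditional_survival is defined only for first-event times "
            "(event_index == 1)")
    if t < 0:
        raise ValueError("additional time t must be >= 0")
    m = d.rate.cumulative(s, s + t)
    return float(math.exp(-m))
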