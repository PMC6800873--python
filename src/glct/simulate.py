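"""ODE integration, survival extraction, and the exact stochastic oracle.

The particle simulator is deliberately exact (event-driven continuous-time
simulation, thinning for time-varying intensities) so that it can serve as
an independent check on every ODE builder: occupancy fractions of the
labeled sub-state process converge to the mean-field trajectory at the
usual O(n^{-1/2}) Monte-Carlo rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .builders import GLCTModel, ODESystem
from .distributions import (CompetingDist, ErlangParams, EventTimeDist,
                            MaxDist, MixtureDist, RateFunction, SeriesDist)
from .phasetype import PhaseTypeRep

CSV_FLOAT_FORMAT = "%.12g"


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """An ODE solution sampled on a strictly increasing time grid."""

    times: np.ndarray                   # shape (T,)
    states: np.ndarray                  # shape (T, d)
    state_labels: list[str]
    observables: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.states = np.asarray(self.states, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.states.shape != (len(self.times), len(self.state_labels)):
            raise ValueError("state array shape inconsistent with labels/grid")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.state_labels)
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False,
                               float_format=CSV_FLOAT_FORMAT)

    def to_json_meta(self) -> str:
        return json.dumps(self.meta, sort_keys=True)


def integrate(sys: ODESystem, horizon: float, grid=201,
              rtol: float = 1e-8, atol: float = 1e-10,
              initial: np.ndarray | None = None,
              include_inflow: bool = True,
              method: str = "DOP853") -> Trajectory:
    """Integrate an :class:`ODESystem` with local error control.

    ``grid`` is either a point count for a uniform grid on ``[0, horizon]``
    or an explicit array of output times.  ``include_inflow=False`` drops
    the external inflow term (impulse-response mode).
    """
    if np.isscalar(grid):
        t_eval = np.linspace(0.0, float(horizon), int(grid))
    else:
        t_eval = np.asarray(grid, float)
    x0 = sys.initial if initial is None else np.asarray(initial, float)
    rhs = sys.rhs if include_inflow else sys.flow
    sol = solve_ivp(rhs, (t_eval[0], t_eval[-1]), x0, method=method,
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    states = sol.y.T
    obs = {name: states @ w for name, w in sys.observables.items()}
    return Trajectory(times=t_eval, states=states,
                      state_labels=list(sys.state_labels),
                      observables=obs,
                      meta={"rtol": rtol, "atol": atol, "method": method})


def survival_from_model(sys: ODESystem, t_grid, rtol: float = 1e-10,
                        atol: float = 1e-12, method: str = "DOP853"):
    """The dwell-time survival function implied by a built model.

    Places a unit impulse on the entry states (per the model's entry
    distribution), switches external inflow off, integrates, and returns
    ``(survival, density)`` series: the total-X occupancy and the exit
    flux out of X.
    """
    if "X_total" not in sys.observables:
        raise ValueError("system has no total-X observable")
    t_grid = np.asarray(t_grid, float)
    traj = integrate(sys, t_grid[-1], grid=t_grid, rtol=rtol, atol=atol,
                     initial=sys.entry_weights, include_inflow=False,
                     method=method)
    survival = traj.observables["X_total"]
    if sys.exit_flow is not None:
        density = np.array([sys.exit_flow(t, x)
                            for t, x in zip(traj.times, traj.states)])
    else:
        density = -np.gradient(survival, t_grid)
    return survival, density


# --------------------------------------------------------------------------
# exact dwell-time sampling
# --------------------------------------------------------------------------

def _sample_nhpp_event_time(rate: RateFunction, k: int, tau: float,
                            rng: np.random.Generator,
                            chunk: float = 1.0) -> float:
    """k-th event time after tau of a Poisson process, by Ogata thinning."""
    if rate.is_constant:
        if rate.value == 0:
            return np.inf
        return tau + rng.gamma(shape=k, scale=1.0 / rate.value)
    t = tau
    events = 0
    for _ in range(1_000_000):
        bound = rate.bound_on(t, t + chunk)
        if bound <= 0:
            t += chunk
            continue
        s = t
        while True:
            s += rng.exponential(1.0 / bound)
            if s > t + chunk:
                break
            if rng.uniform() * bound <= rate.evaluate(s):
                events += 1
                if events == k:
                    return s
        t += chunk
    raise RuntimeError("thinning failed to produce the requested event")


def sample_dwell(d, n: int, seed: int, tau: float = 0.0) -> np.ndarray:
    """Exact dwell-time samples for any supported dwell specification.

    Erlang: sum of k exponentials; mixtures: categorical choice then the
    component; min/max: componentwise extremum; series: sum; NHPP event
    times: thinning (requires a rate bound); phase-type: continuous-time
    jump-chain simulation.  Reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = np.random.default_rng(seed)
    if isinstance(d, ErlangParams):
        return rng.gamma(shape=d.shape, scale=1.0 / d.rate, size=n)
    if isinstance(d, EventTimeDist):
        if d.rate.is_constant:
            return rng.gamma(shape=d.event_index, scale=1.0 / d.rate.value,
                             size=n)
        return np.array([
            _sample_nhpp_event_time(d.rate, d.event_index, tau, rng) - tau
            for _ in range(n)])
    if isinstance(d, MixtureDist):
        w = d._weights_at(tau)
        choices = rng.choice(len(d.components), size=n, p=w)
        out = np.empty(n)
        for i, c in enumerate(d.components):
            mask = choices == i
            cnt = int(mask.sum())
            if cnt:
                out[mask] = _sample_component(c, cnt, rng, tau)
        return out
    if isinstance(d, CompetingDist):
        cols = [_sample_component(c, n, rng, tau) for c in d.components]
        return np.min(np.column_stack(cols), axis=1)
    if isinstance(d, MaxDist):
        cols = [rng.gamma(shape=c.shape, scale=1.0 / c.rate, size=n)
                for c in d.components]
        return np.max(np.column_stack(cols), axis=1)
    if isinstance(d, SeriesDist):
        cols = [_sample_component(c, n, rng, tau) for c in d.components]
        return np.sum(np.column_stack(cols), axis=1)
    if isinstance(d, PhaseTypeRep):
        return _sample_phase_type(d, n, rng)
    raise TypeError(f"unsupported dwell spec {type(d).__name__}")


def _sample_component(c: EventTimeDist, n: int, rng: np.random.Generator,
                      tau: float) -> np.ndarray:
    if c.rate.is_constant:
        if c.rate.value == 0:
            return np.full(n, np.inf)
        return rng.gamma(shape=c.event_index, scale=1.0 / c.rate.value,
                         size=n)
    return np.array([
        _sample_nhpp_event_time(c.rate, c.event_index, tau, rng) - tau
        for _ in range(n)])


def _sample_phase_type(g: PhaseTypeRep, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    lam = -np.diagonal(g.subgenerator)
    nstate = g.n
    full = np.hstack([g.subgenerator, g.exit_block]).copy()
    full[np.arange(nstate), np.arange(nstate)] = 0.0
    probs = np.zeros_like(full)
    for i in range(nstate):
        if lam[i] > 0:
            probs[i] = full[i] / lam[i]
    out = np.empty(n)
    for s in range(n):
        state = rng.choice(nstate, p=g.initial)
        t = 0.0
        while True:
            if lam[state] <= 0:
                t = np.inf
                break
            t += rng.exponential(1.0 / lam[state])
            nxt = rng.choice(nstate + g.m, p=probs[state])
            if nxt >= nstate:
                break
            state = nxt
        out[s] = t
    return out


# --------------------------------------------------------------------------
# ensemble simulation of the labeled sub-state process
# --------------------------------------------------------------------------

@dataclass
class Ensemble:
    """Occupancy counts of a finite-particle simulation on a time grid."""

    n_particles: int
    seed: int
    times: np.ndarray
    state_labels: list[str]            # X sub-states then recipient labels
    state_counts: np.ndarray           # shape (T, n_states), right-continuous
    dwell_samples: np.ndarray          # total time each particle spent in X

    def occupancy_fractions(self) -> np.ndarray:
        return self.state_counts / self.n_particles

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.state_counts, columns=self.state_labels)
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False,
                               float_format=CSV_FLOAT_FORMAT)

    def to_json_meta(self) -> str:
        return json.dumps({"seed": self.seed,
                           "n_particles": self.n_particles},
                          sort_keys=True)


def simulate_ensemble(model: GLCTModel, n_particles: int, horizon: float,
                      seed: int, grid=201) -> Ensemble:
    """Exact event-driven simulation of n particles through the sub-states.

    All particles start at t = 0, distributed over the X sub-states by the
    model's entry distribution (the finite-population analogue of the unit
    impulse).  Each particle follows the labeled jump process: an
    exponential (or thinned nonhomogeneous) waiting time in its current
    sub-state, then a categorical draw over the routing row.  Recipient
    states are absorbing here; compare against an ODE model built with
    sink recipients.  Per-particle random streams are derived from
    ``(seed, particle index)``, so results do not depend on execution
    order.
    """
    if np.isscalar(grid):
        t_grid = np.linspace(0.0, float(horizon), int(grid))
    else:
        t_grid = np.asarray(grid, float)
    n = model.n
    m = model.m
    labels = list(model.substate_labels) + [r.label for r in model.recipients]
    counts = np.zeros((len(t_grid), n + m), dtype=np.int64)
    dwell = np.empty(n_particles)

    constant = all(r.is_constant for r in model.rates)
    if constant:
        rate_vals = np.array([r.value for r in model.rates])
        px0 = model.within_routing(0.0)
        py0 = model.exit_routing(0.0) if m else np.zeros((n, 0))
        rows0 = np.hstack([px0, py0])

    entry_p = model.entry_weights

    master = np.random.SeedSequence(seed)
    child_seeds = master.spawn(n_particles)

    for p in range(n_particles):
        rng = np.random.default_rng(child_seeds[p])
        state = int(rng.choice(n, p=entry_p))
        t = 0.0
        path_times = [0.0]
        path_states = [state]
        while True:
            if constant:
                lam = rate_vals[state]
                if lam <= 0:
                    t = np.inf
                    break
                t += rng.exponential(1.0 / lam)
                if t > t_grid[-1]:
                    break
                row = rows0[state]
            else:
                rf = model.rates[state]
                t_next = _sample_nhpp_event_time(rf, 1, t, rng)
                if not np.isfinite(t_next) or t_next > t_grid[-1]:
                    t = t_next
                    break
                t = t_next
                row = np.hstack([model.within_routing(t)[state],
                                 model.exit_routing(t)[state]]) if m else \
                    model.within_routing(t)[state]
            nxt = int(rng.choice(n + m, p=row))
            path_times.append(t)
            path_states.append(nxt)
            if nxt >= n:       # absorbed into a recipient state
                break
            state = nxt
        dwell[p] = path_times[-1] if path_states[-1] >= n else np.inf
        # accumulate right-continuous occupancy on the grid
        seg_end = path_times[1:] + [np.inf]
        for s, (ta, tb) in zip(path_states, zip(path_times, seg_end)):
            lo = np.searchsorted(t_grid, ta, side="left")
            hi = np.searchsorted(t_grid, tb, side="left")
            counts[lo:hi, s] += 1

    return Ensemble(n_particles=n_particles, seed=seed, times=t_grid,
                    state_labels=labels, state_counts=counts,
                    dwell_samples=dwell)
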