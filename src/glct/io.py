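"""Declarative model specifications (YAML/JSON) and their loader.

A model-spec document describes one builder invocation: the dwell-time
assumption for the focal state, inflow and routing, recipient states, and
a simulation block.  Rate functions are restricted to a safe vocabulary —
``constant``, ``sinusoidal`` (a + b sin(omega t + phi)) and
``piecewise_linear`` — so loading a spec never executes user code;
library users may of course pass arbitrary callables in-process.

Schema sketch (YAML)::

    schema_version: 1
    model:
      kind: erlang_chain          # or event_chain, proportional, mixture,
                                  # competing, series, max, phase_type, glct
      ...kind-specific fields...
      recipients:
        - {label: Y, dwell: {type: sink}}
    simulation:
      horizon: 10.0
      grid: 201
      rtol: 1.0e-8
      atol: 1.0e-10
      seed: 0
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import builders, phasetype
from .builders import (GLCTModel, IntermediateSpec, ODESystem, RecipientSpec,
                       build_competing, build_glct, build_mixture,
                       build_proportional_outputs, build_series, build_max,
                       glct_from_phasetype)
from .distributions import (CompetingDist, ErlangParams, EventTimeDist,
                            MixtureDist, RateFunction, ValidationError)
from .phasetype import PhaseTypeRep

SCHEMA_VERSION = 1

KINDS = ("erlang_chain", "event_chain", "proportional", "mixture",
         "competing", "series", "max", "phase_type", "glct")


class SpecError(ValidationError):
    """A model-spec document is malformed; the message carries the field path."""


def _fail(path: str, msg: str):
    raise SpecError(f"{path}: {msg}")


def _require(d: dict, key: str, path: str):
    if key not in d:
        _fail(f"{path}.{key}", "missing required field")
    return d[key]


def _finite(x, path: str) -> float:
    try:
        v = float(x)
    except (TypeError, ValueError):
        _fail(path, f"expected a number, got {x!r}")
    if not math.isfinite(v):
        _fail(path, f"value must be finite, got {x!r}")
    return v


# --------------------------------------------------------------------------
# rate / inflow expressions
# --------------------------------------------------------------------------

def parse_rate(d, path: str) -> RateFunction:
    if isinstance(d, (int, float)):
        return RateFunction.constant(_finite(d, path))
    if not isinstance(d, dict) or "type" not in d:
        _fail(path, "rate must be a number or a typed mapping")
    kind = d["type"]
    if kind == "constant":
        return RateFunction.constant(_finite(_require(d, "value", path), path))
    if kind == "sinusoidal":
        return RateFunction.sinusoidal(
            _finite(_require(d, "a", path), f"{path}.a"),
            _finite(_require(d, "b", path), f"{path}.b"),
            _finite(d.get("omega", 1.0), f"{path}.omega"),
            _finite(d.get("phi", 0.0), f"{path}.phi"))
    if kind == "piecewise_linear":
        return RateFunction.piecewise_linear(
            [_finite(x, f"{path}.times") for x in _require(d, "times", path)],
            [_finite(x, f"{path}.values") for x in _require(d, "values", path)])
    _fail(f"{path}.type", f"unknown rate expression type {kind!r}")


def rate_to_dict(r: RateFunction):
    if not r.is_constant:
        raise SpecError("only constant rates can be serialized automatically")
    return {"type": "constant", "value": r.value}


def _parse_inflow(d, path: str):
    if d is None:
        return 0.0
    rf = parse_rate(d, path)   # inflows share the rate vocabulary
    return rf.evaluate if not rf.is_constant else rf.value


def _parse_matrix(d, shape, path: str) -> np.ndarray:
    arr = np.asarray(d, dtype=float)
    if arr.shape != tuple(shape):
        _fail(path, f"expected shape {tuple(shape)}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        _fail(path, "matrix entries must be finite")
    return arr


def _check_simplex_rows(arr: np.ndarray, path: str):
    rows = arr.sum(axis=1)
    for i, s in enumerate(rows):
        if abs(s - 1.0) > 1e-9:
            _fail(f"{path}[{i}]", f"row sums to {s!r}, not 1")
    if np.any(arr < 0):
        _fail(path, "entries must be >= 0")


def _parse_recipient(d: dict, path: str) -> RecipientSpec:
    label = _require(d, "label", path)
    dwell = d.get("dwell", {"type": "sink"})
    kind = dwell.get("type", "sink")
    inflow = _parse_inflow(d.get("inflow"), f"{path}.inflow")
    if kind == "sink":
        return RecipientSpec.sink(label, inflow)
    if kind == "exponential":
        return RecipientSpec.exponential(
            label, parse_rate(_require(dwell, "rate", f"{path}.dwell"),
                              f"{path}.dwell.rate"), inflow)
    if kind == "erlang":
        return RecipientSpec.erlang(
            label,
            _finite(_require(dwell, "rate", f"{path}.dwell"),
                    f"{path}.dwell.rate"),
            int(_require(dwell, "shape", f"{path}.dwell")), inflow)
    _fail(f"{path}.dwell.type", f"unknown recipient dwell type {kind!r}")


def _parse_component(d: dict, path: str) -> EventTimeDist:
    return EventTimeDist(
        parse_rate(_require(d, "rate", path), f"{path}.rate"),
        int(_require(d, "shape", path)))


# --------------------------------------------------------------------------
# documents
# --------------------------------------------------------------------------

@dataclass
class ModelSpecDocument:
    """A parsed model specification plus its simulation settings."""

    raw: dict
    kind: str
    simulation: dict = field(default_factory=dict)

    def build(self) -> ODESystem:
        return _build_from_dict(self.raw["model"])

    @property
    def horizon(self) -> float:
        return float(self.simulation.get("horizon", 10.0))

    @property
    def grid(self) -> int:
        return int(self.simulation.get("grid", 201))

    @property
    def rtol(self) -> float:
        return float(self.simulation.get("rtol", 1e-8))

    @property
    def atol(self) -> float:
        return float(self.simulation.get("atol", 1e-10))

    @property
    def seed(self) -> int:
        return int(self.simulation.get("seed", 0))


def load_spec(path) -> ModelSpecDocument:
    """Load and validate a YAML or JSON model-spec file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return parse_spec(raw)


def parse_spec(raw: dict) -> ModelSpecDocument:
    if not isinstance(raw, dict):
        raise SpecError("document root must be a mapping")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        _fail("schema_version", f"unsupported version {version!r}")
    model = _require(raw, "model", "$")
    kind = _require(model, "kind", "$.model")
    if kind not in KINDS:
        _fail("$.model.kind", f"unknown kind {kind!r}; expected one of {KINDS}")
    _build_from_dict(model)   # validate eagerly: all errors at load time
    return ModelSpecDocument(raw=raw, kind=kind,
                             simulation=raw.get("simulation", {}))


def save_spec(doc_or_raw, path) -> None:
    """Write a spec document; round-trips with :func:`load_spec`."""
    raw = doc_or_raw.raw if isinstance(doc_or_raw, ModelSpecDocument) \
        else doc_or_raw
    text = json.dumps(raw, indent=2, sort_keys=True) \
        if str(path).endswith(".json") else yaml.safe_dump(raw, sort_keys=True)
    Path(path).write_text(text)


def model_to_spec(model: GLCTModel, simulation: dict | None = None) -> dict:
    """Serialize a constant-parameter general model to a spec dict."""
    n, m = model.n, model.m
    rates = [rate_to_dict(r) for r in model.rates]
    raw = {
        "schema_version": SCHEMA_VERSION,
        "model": {
            "kind": "glct",
            "labels": list(model.substate_labels),
            "rates": rates,
            "within": np.asarray(model.within_routing(0.0)).tolist(),
            "exit": np.asarray(model.exit_routing(0.0)).tolist(),
            "entry": np.asarray(model.entry_weights).tolist(),
            "inflows": [float(v) for v in np.asarray(model.inflows(0.0))],
            "recipients": [
                {"label": r.label, "dwell": {"type": "sink"}}
                for r in model.recipients],
        },
    }
    if simulation:
        raw["simulation"] = dict(simulation)
    return raw


# --------------------------------------------------------------------------
# builder dispatch
# --------------------------------------------------------------------------

def _recipients(model: dict, path: str) -> list[RecipientSpec]:
    recs = model.get("recipients", [{"label": "Y", "dwell": {"type": "sink"}}])
    return [_parse_recipient(r, f"{path}.recipients[{i}]")
            for i, r in enumerate(recs)]


def _build_from_dict(model: dict) -> ODESystem:
    kind = model["kind"]
    path = "$.model"
    inflow = _parse_inflow(model.get("inflow"), f"{path}.inflow")
    recs = _recipients(model, path)
    m = len(recs)

    if kind in ("erlang_chain", "event_chain"):
        comp = _parse_component(model, path)
        probs = model.get("probs", [1.0] if m == 1 else None)
        if probs is None:
            _fail(f"{path}.probs", "required when several recipients present")
        probs = np.asarray(probs, float)
        _check_simplex_rows(probs[None, :], f"{path}.probs")
        return build_proportional_outputs(comp, inflow, probs, recs)

    if kind == "proportional":
        comp = _parse_component(model, path)
        probs = np.asarray(_require(model, "probs", path), float)
        _check_simplex_rows(probs[None, :], f"{path}.probs")
        return build_proportional_outputs(comp, inflow, probs, recs)

    if kind == "mixture":
        comps = [_parse_component(c, f"{path}.components[{i}]")
                 for i, c in enumerate(_require(model, "components", path))]
        weights = np.asarray(_require(model, "weights", path), float)
        _check_simplex_rows(weights[None, :], f"{path}.weights")
        routing = _parse_matrix(_require(model, "routing", path),
                                (len(comps), m), f"{path}.routing")
        _check_simplex_rows(routing, f"{path}.routing")
        mix = MixtureDist(weights=tuple(weights), components=tuple(comps))
        return build_mixture(mix, inflow, routing, recs)

    if kind == "competing":
        comps = [_parse_component(c, f"{path}.components[{i}]")
                 for i, c in enumerate(_require(model, "components", path))]
        routing = _parse_matrix(_require(model, "routing", path),
                                (len(comps), m), f"{path}.routing")
        _check_simplex_rows(routing, f"{path}.routing")
        return build_competing(CompetingDist(tuple(comps)), inflow,
                               routing, recs)

    if kind == "series":
        comps = [_parse_component(c, f"{path}.components[{i}]")
                 for i, c in enumerate(_require(model, "components", path))]
        probs = model.get("exit_probs", [1.0] if m == 1 else None)
        if probs is None:
            _fail(f"{path}.exit_probs", "required for several recipients")
        return build_series(comps, inflow, np.asarray(probs, float), recs)

    if kind == "max":
        comps = []
        for i, c in enumerate(_require(model, "components", path)):
            rf = parse_rate(_require(c, "rate", f"{path}.components[{i}]"),
                            f"{path}.components[{i}].rate")
            if not rf.is_constant:
                _fail(f"{path}.components[{i}].rate",
                      "max dwell times require constant rates")
            comps.append(ErlangParams(rf.value, int(c["shape"])))
        if len(recs) != 1:
            _fail(f"{path}.recipients", "max models take a single recipient")
        return build_max(comps, inflow, recs[0])

    if kind == "phase_type":
        rho = np.asarray(_require(model, "initial", path), float)
        gx = _parse_matrix(_require(model, "subgenerator", path),
                           (len(rho), len(rho)), f"{path}.subgenerator")
        gy = model.get("exit_block")
        rep = PhaseTypeRep(initial=rho, subgenerator=gx,
                           exit_block=None if gy is None
                           else np.asarray(gy, float))
        if rep.m != m:
            recs = [RecipientSpec.sink(f"Y{j+1}") for j in range(rep.m)]
        return build_glct(glct_from_phasetype(rep, inflow, recs))

    if kind == "glct":
        labels = list(_require(model, "labels", path))
        n = len(labels)
        rates = [parse_rate(r, f"{path}.rates[{i}]")
                 for i, r in enumerate(_require(model, "rates", path))]
        within = _parse_matrix(_require(model, "within", path), (n, n),
                               f"{path}.within")
        exit_m = _parse_matrix(_require(model, "exit", path), (n, m),
                               f"{path}.exit")
        _check_simplex_rows(np.hstack([within, exit_m]),
                            f"{path}.within|exit")
        inflows = model.get("inflows", [0.0] * n)
        inflow_fs = [_parse_inflow(v, f"{path}.inflows[{i}]")
                     for i, v in enumerate(inflows)]

        def inflow_vec(t):
            return np.array([f(t) if callable(f) else f for f in inflow_fs])

        entry = model.get("entry")
        g = GLCTModel.from_arrays(
            substate_labels=labels, inflows=inflow_vec, rates=rates,
            within=within, exit=exit_m, recipients=recs,
            entry_weights=None if entry is None
            else np.asarray(entry, float))
        return build_glct(g)

    _fail(f"{path}.kind", f"unknown kind {kind!r}")
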