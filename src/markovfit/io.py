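"""File formats: model JSON, protocol YAML, dataset CSV.

Model files use a documented JSON schema::

    {"n_states": 3, "edges": [[1, 2], [2, 3]], "conductance": [0, 1, 0],
     "basis": {"kind": "linear"}, "alpha": [[...], ...], "beta": [[...], ...]}

Parameter arrays round-trip bit-exactly (Python's JSON float encoding is
shortest-repr, which is lossless for float64).  Schema violations are
reported with JSON-path-style locations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .model import MarkovModel, VoltageBasisSpec
from .simulate import Dataset, FeatureSpec, Protocol, ProtocolStep, validate_protocol

__all__ = [
    "model_to_dict", "model_from_dict", "write_model", "read_model",
    "protocol_to_dict", "protocol_from_dict", "write_protocol", "read_protocol",
    "read_dataset", "write_dataset",
]


# -- models -----------------------------------------------------------------

def model_to_dict(model: MarkovModel) -> dict:
    basis = {"kind": model.basis.kind}
    if model.basis.kind == "polynomial":
        basis["order"] = model.basis.order
    if model.basis.kind == "sigmoid":
        basis["a"] = model.basis.a
        basis["b"] = model.basis.b
    return {
        "n_states": model.n_states,
        "edges": [list(e) for e in model.edges],
        "conductance": model.conductance.tolist(),
        "basis": basis,
        "alpha": model.alpha.tolist(),
        "beta": model.beta.tolist(),
    }


def _require(d: dict, key: str, loc: str):
    if key not in d:
        raise SchemaError("missing required field", location=f"{loc}.{key}")
    return d[key]


def model_from_dict(d: dict, loc: str = "$") -> MarkovModel:
    if not isinstance(d, dict):
        raise SchemaError("expected an object", location=loc)
    n = _require(d, "n_states", loc)
    if not isinstance(n, int) or n < 1:
        raise SchemaError("n_states must be a positive integer", location=f"{loc}.n_states")
    edges_raw = _require(d, "edges", loc)
    edges = []
    for k, e in enumerate(edges_raw):
        if (not isinstance(e, (list, tuple))) or len(e) != 2:
            raise SchemaError("edge must be a pair", location=f"{loc}.edges[{k}]")
        i, j = int(e[0]), int(e[1])
        if not (1 <= i <= n and 1 <= j <= n) or i == j:
            raise SchemaError(f"invalid edge [{i}, {j}]", location=f"{loc}.edges[{k}]")
        edges.append((i, j))
    braw = _require(d, "basis", loc)
    try:
        basis = VoltageBasisSpec(
            kind=braw.get("kind", "linear"),
            order=int(braw.get("order", 2)),
            a=float(braw.get("a", -40.0)),
            b=float(braw.get("b", 15.0)),
        )
    except (ValueError, AttributeError) as err:
        raise SchemaError(str(err), location=f"{loc}.basis") from err
    conductance = np.asarray(_require(d, "conductance", loc), dtype=float)
    if conductance.shape != (n,):
        raise SchemaError(f"length {conductance.shape[0] if conductance.ndim else '?'} != n_states",
                          location=f"{loc}.conductance")
    F = basis.dimension
    alpha = np.asarray(_require(d, "alpha", loc), dtype=float)
    if alpha.shape != (n, F):
        raise SchemaError(f"shape {list(alpha.shape)} != [{n}, {F}]", location=f"{loc}.alpha")
    beta = np.asarray(_require(d, "beta", loc), dtype=float)
    if beta.shape != (len(edges), F):
        raise SchemaError(f"shape {list(beta.shape)} != [{len(edges)}, {F}]",
                          location=f"{loc}.beta")
    return MarkovModel(n, edges, conductance, alpha, beta, basis)


def write_model(model: MarkovModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2) + "\n")


def read_model(path) -> MarkovModel:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise SchemaError(f"invalid JSON: {err}", location="$") from err
    return model_from_dict(d)


# -- protocols --------------------------------------------------------------

def protocol_to_dict(protocol: Protocol) -> dict:
    f = protocol.feature
    feature = {"kind": f.kind, "normalization": f.normalization, "step": f.step}
    if f.ref_step is not None:
        feature["ref_step"] = f.ref_step
    if f.trace_dt is not None:
        feature["trace_dt"] = f.trace_dt
    return {
        "name": protocol.name,
        "holding_potential": protocol.holding_potential,
        "reversal_potential": protocol.reversal_potential,
        "sweep": {"name": protocol.sweep_name, "values": list(protocol.sweep_values)},
        "steps": [
            {"voltage": s.voltage, "duration": s.duration,
             "record": s.record, **({"dt": s.dt} if s.record else {})}
            for s in protocol.steps
        ],
        "feature": feature,
    }


def protocol_from_dict(d: dict, loc: str = "$") -> Protocol:
    if not isinstance(d, dict):
        raise SchemaError("expected a mapping", location=loc)
    name = _require(d, "name", loc)
    sweep = _require(d, "sweep", loc)
    values = _require(sweep, "values", f"{loc}.sweep")
    steps = []
    for k, s in enumerate(_require(d, "steps", loc)):
        sloc = f"{loc}.steps[{k}]"
        voltage = _require(s, "voltage", sloc)
        duration = _require(s, "duration", sloc)
        for fieldname, val in (("voltage", voltage), ("duration", duration)):
            if not (val == "sweep" or isinstance(val, (int, float))):
                raise SchemaError("must be a number or \"sweep\"",
                                  location=f"{sloc}.{fieldname}")
        steps.append(ProtocolStep(
            voltage=voltage if voltage == "sweep" else float(voltage),
            duration=duration if duration == "sweep" else float(duration),
            record=bool(s.get("record", False)),
            dt=float(s.get("dt", 0.01)),
        ))
    fraw = _require(d, "feature", loc)
    feature = FeatureSpec(
        kind=_require(fraw, "kind", f"{loc}.feature"),
        normalization=fraw.get("normalization", "none"),
        step=int(fraw.get("step", 0)),
        ref_step=fraw.get("ref_step"),
        trace_dt=fraw.get("trace_dt"),
    )
    proto = Protocol(
        name=str(name),
        holding_potential=float(_require(d, "holding_potential", loc)),
        steps=tuple(steps),
        sweep_name=str(sweep.get("name", "voltage")),
        sweep_values=tuple(float(v) for v in values),
        feature=feature,
        reversal_potential=float(_require(d, "reversal_potential", loc)),
    )
    validate_protocol(proto)  # raises ProtocolError on rule violations
    return proto


def write_protocol(protocol: Protocol, path) -> None:
    Path(path).write_text(yaml.safe_dump(protocol_to_dict(protocol), sort_keys=False))


def read_protocol(path) -> Protocol:
    try:
        d = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as err:
        raise SchemaError(f"invalid YAML: {err}", location="$") from err
    return protocol_from_dict(d)


# -- datasets ---------------------------------------------------------------

def read_dataset(path) -> Dataset:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["protocol", "x", "y", "weight"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing}", location="$")
    bad = df.index[df["weight"] <= 0]
    if len(bad):
        raise SchemaError("weight must be positive", location=f"$.rows[{int(bad[0])}]")
    return Dataset(df[required].copy())


def write_dataset(dataset: Dataset, path) -> None:
    dataset.df.to_csv(path, index=False)
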