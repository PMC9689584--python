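"""Plain-text serialisation: event TSV files and model JSON.

Event TSV dialect: a header line ``symbol<TAB>dwell``, then one event per
row with the dwell in seconds as a decimal.  An optional final comment line
``# censored`` marks the last dwell as still ongoing (observed so far).

Model JSON schema: ``{states, alphabet, allowed_emissions, successor,
emission_prob, dwell}``, with ``dwell`` mapping each state to a tagged
parameter object.  Parametric kinds round-trip bit-exactly; the neural kind
stores its weight arrays and support interval.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import density as _density
from .model_core import (
    DwellModel,
    EventSequence,
    ExponentialDwell,
    InverseGaussianDwell,
    MixtureDwell,
    Topology,
    UhsMm,
    UniformDwell,
)

__all__ = ["read_events_tsv", "write_events_tsv", "read_model_json",
           "write_model_json", "dwell_to_dict", "dwell_from_dict"]


def write_events_tsv(seq: EventSequence, path) -> None:
    lines = ["symbol\tdwell"]
    for x, tau in zip(seq.symbols, seq.dwells):
        lines.append(f"{x}\t{float(tau)!r}")
    if seq.final_censored:
        lines.append("# censored")
    Path(path).write_text("\n".join(lines) + "\n")


def read_events_tsv(path) -> EventSequence:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or lines[0].split("\t")[:2] != ["symbol", "dwell"]:
        raise ValueError("event TSV must start with a 'symbol<TAB>dwell' header")
    censored = False
    if lines[-1].strip().startswith("#"):
        if lines[-1].strip() != "# censored":
            raise ValueError(f"unrecognised trailing comment: {lines[-1]!r}")
        censored = True
        lines = lines[:-1]
    symbols, dwells = [], []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {i}: expected 2 tab-separated fields")
        x, tau = parts[0], float(parts[1])
        if tau <= 0:
            raise ValueError(f"line {i}: dwell must be positive, got {tau}")
        if symbols and symbols[-1] == x:
            raise ValueError(f"line {i}: consecutive symbols must differ")
        symbols.append(x)
        dwells.append(tau)
    return EventSequence(symbols, np.array(dwells), final_censored=censored)


# ---------------------------------------------------------------------------
# Dwell-model (de)serialisation
# ---------------------------------------------------------------------------


def dwell_to_dict(d: DwellModel) -> dict:
    if isinstance(d, InverseGaussianDwell):
        return {"kind": "inverse_gaussian", "mean": d.mu, "scale": d.lam}
    if isinstance(d, ExponentialDwell):
        return {"kind": "exponential", "mean": d.mean}
    if isinstance(d, UniformDwell):
        return {"kind": "uniform", "lo": d.lo, "hi": d.hi}
    if isinstance(d, MixtureDwell):
        return {
            "kind": "mixture",
            "weights": d.weights.tolist(),
            "components": [dwell_to_dict(c) for c in d.components],
        }
    if isinstance(d, _density.KernelDensity):
        return {"kind": "kernel", "samples": d.samples.tolist(),
                "bandwidth": d.bandwidth}
    if isinstance(d, _density.KnnDensity):
        return {"kind": "knn", "samples": d.samples.tolist(), "k": d.k}
    if isinstance(d, _density.NeuralDensity):
        return {
            "kind": "neural",
            "support": [d.t_lo, d.t_hi],
            "log_center": d.log_center,
            "log_scale": d.log_scale,
            "normalizer": d.normalizer,
            "grid_points": d.grid_points,
            "weights": [W.tolist() for W in d.net.W],
            "biases": [b.tolist() for b in d.net.b],
        }
    raise TypeError(f"cannot serialise dwell model of type {type(d).__name__}")


def dwell_from_dict(obj: dict) -> DwellModel:
    kind = obj["kind"]
    if kind == "inverse_gaussian":
        return InverseGaussianDwell(obj["mean"], obj["scale"])
    if kind == "exponential":
        return ExponentialDwell(obj["mean"])
    if kind == "uniform":
        return UniformDwell(obj["lo"], obj["hi"])
    if kind == "mixture":
        return MixtureDwell(obj["weights"],
                            [dwell_from_dict(c) for c in obj["components"]])
    if kind == "kernel":
        return _density.KernelDensity(np.array(obj["samples"]), obj["bandwidth"])
    if kind == "knn":
        return _density.KnnDensity(np.array(obj["samples"]), obj["k"])
    if kind == "neural":
        W = [np.array(w) for w in obj["weights"]]
        layers, width = len(W), (W[0].shape[1] if len(W) > 1 else 1)
        net = _density._MLP(layers, width, np.random.default_rng(0))
        net.W = W
        net.b = [np.array(b) for b in obj["biases"]]
        return _density.NeuralDensity(
            net, tuple(obj["support"]), obj["log_center"], obj["log_scale"],
            obj["normalizer"], obj["grid_points"],
        )
    raise ValueError(f"unknown dwell kind {kind!r}")


def write_model_json(model: UhsMm, path) -> None:
    topo = model.topology
    obj = {
        "states": list(topo.states),
        "alphabet": sorted(topo.alphabet),
        "allowed_emissions": {g: sorted(topo.allowed_emissions[g])
                              for g in topo.states},
        "successor": {g: dict(topo.successor[g]) for g in topo.states},
        "emission_prob": {g: dict(model.emission_prob[g]) for g in topo.states},
        "dwell": {g: dwell_to_dict(model.dwell[g]) for g in topo.states},
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_model_json(path) -> UhsMm:
    obj = json.loads(Path(path).read_text())
    topo = Topology(
        tuple(obj["states"]),
        {g: frozenset(v) for g, v in obj["allowed_emissions"].items()},
        {g: dict(v) for g, v in obj["successor"].items()},
    )
    return UhsMm(
        topo,
        {g: dict(v) for g, v in obj["emission_prob"].items()},
        {g: dwell_from_dict(v) for g, v in obj["dwell"].items()},
    )
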