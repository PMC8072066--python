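"""Round-trippable model configuration files (YAML).

A config bundles the topology, kinetic rates (with their time unit), the
initial state and any per-label initial labeling frequencies, so a model
instance can be written to disk and reconstructed losslessly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .model import InitialState, KineticRates, ModelTopology


def model_to_dict(topology: ModelTopology, rates: KineticRates,
                  init: InitialState | None = None) -> dict:
    d: dict = {
        "topology": {"compartments": list(topology.compartments)},
        "rates": {
            "unit": "per_day",
            "alpha": rates.alpha.tolist(),
            "beta": rates.beta.tolist(),
        },
    }
    if rates.lam is not None:
        d["rates"]["lambda"] = rates.lam.tolist()
        d["rates"]["delta"] = rates.delta.tolist()
    if init is not None:
        d["initial_state"] = {"n0": init.n0.tolist()}
        if init.f0 is not None:
            f0 = init.f0
            if isinstance(f0, Mapping):
                d["initial_state"]["f0"] = {k: np.asarray(v).tolist() for k, v in f0.items()}
            else:
                d["initial_state"]["f0"] = np.asarray(f0).tolist()
    return d


def model_from_dict(d: dict) -> tuple[ModelTopology, KineticRates, InitialState | None]:
    topo = ModelTopology(tuple(d["topology"]["compartments"]))
    r = d["rates"]
    if r.get("unit", "per_day") != "per_day":
        raise ValueError("only per_day rate configs are supported")
    if "lambda" in r:
        rates = KineticRates(alpha=np.asarray(r["alpha"], float),
                             beta=np.asarray(r["beta"], float),
                             lam=np.asarray(r["lambda"], float),
                             delta=np.asarray(r["delta"], float))
    else:
        rates = KineticRates(alpha=np.asarray(r["alpha"], float),
                             beta=np.asarray(r["beta"], float))
    init = None
    if "initial_state" in d:
        s = d["initial_state"]
        f0 = s.get("f0")
        if isinstance(f0, dict):
            f0 = {k: np.asarray(v, float) for k, v in f0.items()}
        elif f0 is not None:
            f0 = np.asarray(f0, float)
        init = InitialState(n0=np.asarray(s["n0"], float), f0=f0)
    return topo, rates, init


def save_model(path, topology: ModelTopology, rates: KineticRates,
               init: InitialState | None = None) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(topology, rates, init),
                                         sort_keys=False))


def load_model(path) -> tuple[ModelTopology, KineticRates, InitialState | None]:
    return model_from_dict(yaml.safe_load(Path(path).read_text()))
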