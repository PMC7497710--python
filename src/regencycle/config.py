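"""Model configuration files and result records.

Two config layouts are accepted (YAML or JSON):

1. A generic switching model::

       states:
         - {label: diffusing, law: {family: exp_diffusion, params: {r: 1.0, D: 1.0}}}
         - {label: transport, law: {family: exp_drift, params: {r: 0.5, v: 1.0}}}
       P: [[0, 1], [1, 0]]        # or: A: [[...]] with v: [...] and d: [...]
       base_state: 0

   When ``A`` is given the CTMC is embedded automatically and the rate matrix
   is retained so the homogenization cross-check can run.

2. A named motor model::

       model: cooperative        # cooperative | tug_of_war | sliding |
       params: {N: 2, v: 1.0, ...}   # two_state | four_state

Result records are flat dicts (JSON/CSV friendly) with fixed keys:
model_id, method, v_eff, D_eff, run_length, E_dT, E_dX, Var_dT, Var_dX, Cov.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import yaml

from . import motor_models as mm
from .cycle_moments import EffectiveTransport
from .switching_model import (
    RateMatrix,
    SwitchingModel,
    ValidationError,
    embed_ctmc,
    make_state_law,
)

__all__ = ["load_config", "load_model", "save_model", "build_motor_model",
           "result_record", "write_records"]

RECORD_KEYS = ("model_id", "method", "v_eff", "D_eff", "run_length",
               "E_dT", "E_dX", "Var_dT", "Var_dX", "Cov")

_MOTOR_KINDS = ("two_state", "four_state", "cooperative", "tug_of_war", "sliding")


def _read(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def build_motor_model(kind: str, params: dict) -> SwitchingModel:
    """Dispatch a named motor model builder on a plain parameter dict."""
    if kind == "two_state":
        return mm.build_two_state(**params)
    if kind == "four_state":
        return mm.build_four_state(**params)
    if kind == "cooperative":
        return mm.build_cooperative(mm.CooperativeParams(**params))
    if kind == "tug_of_war":
        p = dict(params)
        plus = mm.MotorParams(**p.pop("plus"))
        minus = mm.MotorParams(**p.pop("minus"))
        return mm.build_tug_of_war(mm.TugOfWarParams(plus=plus, minus=minus, **p))
    if kind == "sliding":
        return mm.build_sliding(mm.SlidingParams(**params))
    raise ValidationError(f"unknown motor model {kind!r}; "
                          f"expected one of {_MOTOR_KINDS}")


def load_config(path) -> tuple[SwitchingModel, RateMatrix | None]:
    """Load any supported config; returns the model and, when the config was
    given as a CTMC generator, the rate matrix for the homogenization check."""
    cfg = _read(path)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping")
    if "model" in cfg:
        return build_motor_model(cfg["model"], cfg.get("params", {})), None
    return load_model_dict(cfg)


def load_model(path) -> SwitchingModel:
    return load_config(path)[0]


def load_model_dict(cfg: dict) -> tuple[SwitchingModel, RateMatrix | None]:
    base = int(cfg.get("base_state", 0))
    if "A" in cfg:
        if "v" not in cfg or "d" not in cfg:
            raise ValidationError("CTMC config requires A, v and d")
        rm = RateMatrix(np.asarray(cfg["A"], float),
                        np.asarray(cfg["v"], float),
                        np.asarray(cfg["d"], float))
        return embed_ctmc(rm, base_state=base), rm
    if "states" not in cfg or "P" not in cfg:
        raise ValidationError("config requires either (states, P) or (A, v, d)")
    laws, labels = [], []
    for st in cfg["states"]:
        law = st["law"]
        laws.append(make_state_law(law["family"], **law.get("params", {})))
        labels.append(st.get("label"))
    if any(l is None for l in labels):
        labels = None
    model = SwitchingModel(np.asarray(cfg["P"], float), laws,
                           base_state=base, labels=labels)
    return model, None


def save_model(model: SwitchingModel, path) -> None:
    """Write a switching model back out as a round-trippable YAML config."""
    states = []
    for i, law in enumerate(model.laws):
        entry = {"law": {"family": law.family, "params": dict(law.params)}}
        if law.family == "general":
            entry["law"]["params"] = {
                "E_tau": law.E_tau, "E_tau2": law.E_tau2, "E_xi": law.E_xi,
                "E_xi2": law.E_xi2, "E_tauxi": law.E_tauxi,
            }
        if model.labels is not None:
            entry["label"] = model.labels[i]
        states.append(entry)
    cfg = {
        "states": states,
        "P": model.P.tolist(),
        "base_state": model.base_state,
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def result_record(model_id: str, et: EffectiveTransport,
                  method: str = "renewal") -> dict:
    """Flat result record with the fixed schema used by all writers."""
    cs = et.cycle_stats
    rec = {
        "model_id": model_id,
        "method": method,
        "v_eff": et.v_eff,
        "D_eff": et.D_eff,
        "run_length": None if math.isnan(et.run_length) else et.run_length,
        "E_dT": cs.E_dT if cs else None,
        "E_dX": cs.E_dX if cs else None,
        "Var_dT": cs.Var_dT if cs else None,
        "Var_dX": cs.Var_dX if cs else None,
        "Cov": cs.Cov_dXdT if cs else None,
    }
    return rec


def write_records(records: list[dict], path, fmt: str = "json") -> None:
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(records, indent=2) + "\n")
    elif fmt == "csv":
        import pandas as pd
        pd.DataFrame(records, columns=RECORD_KEYS).to_csv(
            path, index=False, float_format="%.17g")
    else:
        raise ValidationError(f"unknown format {fmt!r}")
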