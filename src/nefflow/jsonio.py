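"""JSON serialization of models (the graph-fixture format).

Layout::

    {
      "dt": 0.001,
      "signals":   [{"name", "shape", "dtype", "initial"}, ...],
      "views":     [{"name", "base", "offset", "shape"}, ...],
      "operators": [{"tag", "roles": {"sets": [...], "incs": [...],
                     "reads": [...], "updates": [...]}, "params": {...}}, ...],
      "probes":    [{"target", "label"}, ...]
    }

Operators reference signals and views by name.  ``UserFunc`` operators are
serializable only when their function is a registered name in
:data:`nefflow.engine.FUNCTIONS`.  Cluster metadata (direct-mode
substitution) is not serialized.  The reader validates all model invariants.
"""

from __future__ import annotations

import json

import numpy as np

from .graph_core import Model, Operator, Signal, SignalView, _ROLE_ORDER

__all__ = ["model_to_dict", "model_from_dict", "write_model", "read_model"]

_DTYPES = {"float64": np.float64, "float32": np.float32, "int64": np.int64}


def model_to_dict(model: Model) -> dict:
    names = {}
    for sig in model.signals:
        if sig.name in names:
            raise ValueError(f"duplicate signal name {sig.name!r}")
        names[sig.name] = sig

    sig_entries = [
        {
            "name": s.name,
            "shape": list(s.shape),
            "dtype": s.dtype.name,
            "initial": s.initial.tolist(),
        }
        for s in model.signals
    ]

    view_entries = []
    view_names: dict[int, str] = {}

    def ref(sig) -> str:
        if not sig.is_view:
            if id(sig) not in {id(s) for s in model.signals}:
                raise ValueError(f"signal {sig.name!r} not in model signal list")
            return sig.name
        vid = id(sig)
        if vid not in view_names:
            vname = f"view_{len(view_names)}"
            view_names[vid] = vname
            view_entries.append({
                "name": vname,
                "base": sig.base.name,
                "offset": sig.offset,
                "shape": list(sig.shape),
            })
        return view_names[vid]

    op_entries = []
    for op in model.operators:
        params = {}
        for key, val in op.params.items():
            if key == "fn":
                if not isinstance(val, str):
                    raise ValueError(
                        "UserFunc with a non-registered callable cannot be "
                        "serialized; use a FUNCTIONS registry name"
                    )
                params[key] = val
            elif isinstance(val, tuple):
                params[key] = list(val)
            else:
                params[key] = val
        op_entries.append({
            "tag": op.tag,
            "roles": {role: [ref(s) for s in getattr(op, role)]
                      for role in _ROLE_ORDER},
            "params": params,
        })

    probe_entries = [
        {"target": ref(p.target), "label": p.label} for p in model.probes
    ]

    return {
        "dt": model.dt,
        "signals": sig_entries,
        "views": view_entries,
        "operators": op_entries,
        "probes": probe_entries,
    }


def model_from_dict(data: dict) -> Model:
    model = Model(dt=float(data.get("dt", 0.001)))
    by_name: dict[str, object] = {}
    for entry in data.get("signals", []):
        dtype = _DTYPES.get(entry.get("dtype", "float64"))
        if dtype is None:
            raise ValueError(f"unsupported dtype {entry.get('dtype')!r}")
        sig = Signal(entry["name"], initial=np.asarray(entry["initial"]),
                     dtype=dtype)
        if tuple(entry["shape"]) != sig.shape:
            raise ValueError(f"signal {sig.name!r}: shape/initial mismatch")
        if sig.name in by_name:
            raise ValueError(f"duplicate signal name {sig.name!r}")
        model.add_signal(sig)
        by_name[sig.name] = sig
    for entry in data.get("views", []):
        base = by_name.get(entry["base"])
        if base is None or base.is_view:
            raise ValueError(f"view {entry['name']!r}: unknown base "
                             f"{entry['base']!r}")
        view = SignalView(base, int(entry["offset"]), tuple(entry["shape"]))
        if entry["name"] in by_name:
            raise ValueError(f"duplicate name {entry['name']!r}")
        by_name[entry["name"]] = view

    def deref(name: str):
        try:
            return by_name[name]
        except KeyError:
            raise ValueError(f"operator references unknown signal {name!r}") \
                from None

    for entry in data.get("operators", []):
        params = dict(entry.get("params", {}))
        if "block_shape" in params:
            params["block_shape"] = tuple(params["block_shape"])
        roles = entry.get("roles", {})
        op = Operator(
            entry["tag"],
            sets=[deref(n) for n in roles.get("sets", [])],
            incs=[deref(n) for n in roles.get("incs", [])],
            reads=[deref(n) for n in roles.get("reads", [])],
            updates=[deref(n) for n in roles.get("updates", [])],
            params=params,
        )
        model.add_op(op)

    for entry in data.get("probes", []):
        model.add_probe(deref(entry["target"]), entry.get("label"))

    model.clusters = []
    model.validate()
    return model


def write_model(model: Model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def read_model(path) -> Model:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
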