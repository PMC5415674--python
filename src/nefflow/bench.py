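"""Benchmark harness: timed build, warm-up, and timed simulation.

Protocol per trial: the model build (plus optimization when enabled) is
timed as *build time*; 10 untimed warm-up steps pre-fill the memory buffers;
then 1,000 timed steps (one simulated second at dt = 1 ms) are reported as
*simulation time*.  Means over five trials are reported by default.
Wall-clock numbers are inherently hardware-dependent; operator counts and
probe-trace equivalence are the reproducible surface.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import pandas as pd

from .engine import SimulatorState, run, step, to_direct
from .graph_core import Model, build_dependency_graph, toposort
from .netgen import (
    CircConvSpec,
    SplitEnsembleSpec,
    fig3_fixture,
    gen_circconv_model,
    gen_random_model,
    gen_split_ensemble_model,
)
from .optimizer import optimize

__all__ = ["BenchResult", "build_model", "bench", "report", "load_report"]

N_WARMUP = 10
N_TIMED = 1000


@dataclass
class BenchResult:
    """Aggregated benchmark outcome (means over trials + raw per-trial data)."""

    kind: str
    params: dict
    optimized: bool
    trials: int
    build_time: float = 0.0
    sim_time: float = 0.0
    ops_before: int = 0
    ops_after: int = 0
    warmup_steps: int = N_WARMUP
    timed_steps: int = N_TIMED
    raw_build_times: list = field(default_factory=list)
    raw_sim_times: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "params": self.params,
            "optimized": self.optimized,
            "trials": self.trials,
            "build_time": self.build_time,
            "sim_time": self.sim_time,
            "ops_before": self.ops_before,
            "ops_after": self.ops_after,
            "warmup_steps": self.warmup_steps,
            "timed_steps": self.timed_steps,
            "raw_build_times": self.raw_build_times,
            "raw_sim_times": self.raw_sim_times,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BenchResult":
        return cls(**data)


def build_model(spec) -> Model:
    """Build a model from a generator spec (or pass a Model through)."""
    if isinstance(spec, Model):
        return spec
    if isinstance(spec, CircConvSpec):
        model = gen_circconv_model(spec)
        if spec.mode == "direct":
            model = to_direct(model)
        return model
    if isinstance(spec, SplitEnsembleSpec):
        return gen_split_ensemble_model(spec)
    if isinstance(spec, dict):
        kind = spec.get("kind", "circconv")
        args = {k: v for k, v in spec.items() if k != "kind"}
        if kind == "circconv":
            return build_model(CircConvSpec(**args))
        if kind == "split":
            return build_model(SplitEnsembleSpec(**args))
        if kind == "fig3":
            return fig3_fixture(**args)
        if kind == "random":
            return gen_random_model(**args)
        raise ValueError(f"unknown model kind {kind!r}")
    raise TypeError(f"cannot build a model from {spec!r}")


def bench(model_spec, optimize_flag: bool = True, trials: int = 5,
          n_warmup: int = N_WARMUP, n_timed: int = N_TIMED,
          probe: bool = False):
    """Run the benchmark protocol; returns a :class:`BenchResult`.

    With ``probe=True`` additionally returns the probe traces of a plain
    (untimed) run of the final trial's model, for equivalence checking.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    result = BenchResult(
        kind=model_spec.__class__.__name__ if not isinstance(model_spec, dict)
        else model_spec.get("kind", "?"),
        params=dict(model_spec) if isinstance(model_spec, dict) else
        getattr(model_spec, "__dict__", {}),
        optimized=bool(optimize_flag),
        trials=int(trials),
        warmup_steps=int(n_warmup),
        timed_steps=int(n_timed),
    )
    last_model = None
    for _ in range(trials):
        t0 = time.perf_counter()
        model = build_model(model_spec)
        ops_before = len(model.operators)
        if optimize_flag:
            model, _rep = optimize(model)
        result.raw_build_times.append(time.perf_counter() - t0)
        result.ops_before = ops_before
        result.ops_after = len(model.operators)

        plan = toposort(build_dependency_graph(model.operators))
        state = SimulatorState(model)
        for _ in range(n_warmup):
            step(state, plan)
        warm_index = state.step_index
        t1 = time.perf_counter()
        for _ in range(n_timed):
            step(state, plan)
        result.raw_sim_times.append(time.perf_counter() - t1)
        assert state.step_index - warm_index == n_timed
        last_model = model

    result.build_time = sum(result.raw_build_times) / trials
    result.sim_time = sum(result.raw_sim_times) / trials
    if probe:
        traces = run(last_model, n_timed)
        return result, traces
    return result


def report(results, path=None, fmt: str = "json"):
    """Serialize a list of :class:`BenchResult` to JSON or CSV.

    Returns the serialized object (list of dicts or DataFrame); writes to
    ``path`` when given.
    """
    rows = [r.to_dict() for r in results]
    if fmt == "json":
        if path is not None:
            with open(path, "w") as fh:
                json.dump(rows, fh, indent=1)
        return rows
    if fmt == "csv":
        flat = []
        for row in rows:
            row = dict(row)
            row["params"] = json.dumps(row["params"], default=str)
            row["raw_build_times"] = json.dumps(row["raw_build_times"])
            row["raw_sim_times"] = json.dumps(row["raw_sim_times"])
            flat.append(row)
        frame = pd.DataFrame(flat)
        if path is not None:
            frame.to_csv(path, index=False)
        return frame
    raise ValueError(f"unknown format {fmt!r}")


def load_report(path):
    """Read back a JSON benchmark report."""
    with open(path) as fh:
        rows = json.load(fh)
    return [BenchResult.from_dict(row) for row in rows]
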