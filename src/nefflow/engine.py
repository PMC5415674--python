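"""Step-by-step execution of a dataflow model.

Each simulation step applies every operator once, in a topologically sorted
order, to a set of in-memory buffers (one per base signal).  Operator
semantics:

* ``Reset``           — ``target[:] = value``
* ``Copy``            — ``dst[:] = src`` or ``dst += src``
* ``ElementwiseInc``  — ``Y += A * X``
* ``DotInc``          — ``Y += A @ X``
* ``BsrDotInc``       — ``Y_k += A_k @ X_k`` per dense block ``k`` of a
  block-diagonal matrix; the zero blocks are never materialized, so storage
  grows linearly with the number of blocks.
* ``SimNeurons``      — spiking leaky integrate-and-fire dynamics
  ``tau_rc * dv/dt = J - v`` with exact exponential integration, threshold 1,
  spike amplitude ``1/dt`` and refractory period ``tau_ref``.  The spike time
  within a step is interpolated and carried into the refractory hold so that
  firing rates match the closed-form LIF rate even at coarse ``dt``.
* ``UserFunc``        — arbitrary callable of time or of an input signal.
* ``TimeUpdate``      — advances a step counter / time signal.

*Direct mode* replaces each neuron cluster (encode, nonlinearity, decode) by
a single ``UserFunc`` computing the represented function exactly; see
:func:`to_direct`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .graph_core import (
    GraphError,
    Model,
    Operator,
    ExecutionPlan,
    UserFunc,
    build_dependency_graph,
    toposort,
)

__all__ = [
    "SimulationError",
    "SimulatorState",
    "ProbeData",
    "FUNCTIONS",
    "step",
    "run",
    "to_direct",
    "traces_equivalent",
    "lif_rate",
]


class SimulationError(GraphError):
    """Numeric failure while applying an operator."""


#: Named functions usable by :func:`~nefflow.graph_core.UserFunc` operators.
#: Referencing functions by name keeps models JSON-serializable.
FUNCTIONS = {
    "identity": lambda x: x,
    "product": lambda x: np.asarray([x[0] * x[1]]),
    "zero_time": lambda t: np.zeros(1),
}


class SimulatorState:
    """Mutable buffers plus the simulation clock.

    Buffers exist only for base signals; resolving a view yields a numpy view
    aliasing the base buffer (contiguous, row-major).
    """

    def __init__(self, model: Model):
        self.model = model
        self.dt = model.dt
        self.buffers = {
            id(sig): np.array(sig.initial, dtype=sig.dtype, copy=True)
            for sig in model.signals
        }
        self.t = 0.0
        self.step_index = 0
        self._compiled: dict[int, list] = {}

    def resolve(self, sig) -> np.ndarray:
        """ndarray aliasing the memory of ``sig`` (signal or view)."""
        try:
            buf = self.buffers[id(sig.base)]
        except KeyError:
            raise GraphError(f"signal {sig.base.name!r} has no buffer") from None
        if not sig.is_view:
            return buf
        flat = buf.reshape(-1)
        return flat[sig.offset:sig.offset + sig.size].reshape(sig.shape)


def _compile_op(op: Operator, state: SimulatorState, dt: float):
    """Bind an operator to its buffers, returning a thunk ``f(t)``."""
    tag = op.tag
    if tag == "Reset":
        y = state.resolve(op.sets[0])
        value = op.params["value"]

        def thunk(t, y=y, value=value):
            y[...] = value

    elif tag == "Copy":
        src = state.resolve(op.reads[0])
        dst = state.resolve((op.incs or op.sets)[0])
        if src.size != dst.size:
            raise SimulationError(f"{op!r}: size mismatch")
        src = src.reshape(dst.shape)
        if op.params.get("inc", False):
            def thunk(t, src=src, dst=dst):
                dst += src
        else:
            def thunk(t, src=src, dst=dst):
                dst[...] = src

    elif tag == "ElementwiseInc":
        A = state.resolve(op.reads[0])
        X = state.resolve(op.reads[1])
        Y = state.resolve(op.incs[0])
        if not (A.shape == X.shape == Y.shape):
            raise SimulationError(f"{op!r}: shape mismatch")

        def thunk(t, A=A, X=X, Y=Y):
            Y += A * X

    elif tag == "DotInc":
        A = state.resolve(op.reads[0])
        X = state.resolve(op.reads[1]).reshape(-1)
        Y = state.resolve(op.incs[0]).reshape(-1)
        if A.ndim != 2 or A.shape != (Y.size, X.size):
            raise SimulationError(
                f"{op!r}: A {A.shape} incompatible with X {X.shape}, Y {Y.shape}"
            )

        def thunk(t, A=A, X=X, Y=Y):
            Y += A @ X

    elif tag == "BsrDotInc":
        nb = op.params["n_blocks"]
        m, n = op.params["block_shape"]
        A = state.resolve(op.reads[0])
        X = state.resolve(op.reads[1]).reshape(-1)
        Y = state.resolve(op.incs[0]).reshape(-1)
        if A.shape != (nb * m, n) or X.size != nb * n or Y.size != nb * m:
            raise SimulationError(f"{op!r}: block layout mismatch")
        # per-block matmul keeps the arithmetic identical to the unmerged
        # DotInc operators (same BLAS call on the same elements)
        blocks = [A[k * m:(k + 1) * m] for k in range(nb)]
        xs = [X[k * n:(k + 1) * n] for k in range(nb)]
        ys = [Y[k * m:(k + 1) * m] for k in range(nb)]

        def thunk(t, blocks=blocks, xs=xs, ys=ys):
            for Ak, xk, yk in zip(blocks, xs, ys):
                yk += Ak @ xk

    elif tag == "SimNeurons":
        J = state.resolve(op.reads[0]).reshape(-1)
        out = state.resolve(op.sets[0]).reshape(-1)
        voltage = state.resolve(op.updates[0]).reshape(-1)
        refractory = state.resolve(op.updates[1]).reshape(-1)
        tau_rc = op.params["tau_rc"]
        tau_ref = op.params["tau_ref"]
        inv_dt = 1.0 / dt

        def thunk(t, J=J, out=out, v=voltage, ref=refractory,
                  tau_rc=tau_rc, tau_ref=tau_ref, dt=dt, inv_dt=inv_dt, op=op):
            if not np.all(np.isfinite(J)):
                raise SimulationError(f"{op!r}: non-finite input current")
            ref -= dt
            delta_t = np.clip(dt - ref, 0.0, dt)
            v -= (J - v) * np.expm1(-delta_t / tau_rc)
            spiked = v >= 1.0
            out[...] = 0.0
            out[spiked] = inv_dt
            if spiked.any():
                t_spike = dt + tau_rc * np.log1p(
                    -(v[spiked] - 1.0) / (J[spiked] - 1.0)
                )
                v[spiked] = 0.0
                ref[spiked] = tau_ref + t_spike

    elif tag == "UserFunc":
        fn = op.params["fn"]
        if isinstance(fn, str):
            fn = FUNCTIONS[fn]
        out = state.resolve((op.incs or op.sets)[0])
        x = state.resolve(op.reads[0]) if op.reads else None
        inc = op.params.get("inc", False)

        def thunk(t, fn=fn, out=out, x=x, inc=inc):
            val = fn(t) if x is None else fn(x)
            val = np.asarray(val, dtype=out.dtype).reshape(out.shape)
            if inc:
                out += val
            else:
                out[...] = val

    elif tag == "TimeUpdate":
        step_sig = state.resolve(op.updates[0]).reshape(-1)
        time_sig = state.resolve(op.updates[1]).reshape(-1)

        def thunk(t, step_sig=step_sig, time_sig=time_sig, dt=dt):
            step_sig += 1
            time_sig[...] = step_sig * dt

    else:
        raise GraphError(f"unknown operator tag {tag!r}")
    return thunk


def _compiled(state: SimulatorState, plan: ExecutionPlan):
    thunks = state._compiled.get(id(plan))
    if thunks is None:
        thunks = [_compile_op(op, state, state.dt) for op in plan]
        state._compiled[id(plan)] = thunks
    return thunks


def step(state: SimulatorState, plan: ExecutionPlan) -> SimulatorState:
    """Apply every operator of ``plan`` once, in order; advance t by dt."""
    for thunk in _compiled(state, plan):
        thunk(state.t)
    state.step_index += 1
    state.t = state.step_index * state.dt
    return state


class ProbeData:
    """Sampled probe values: one (n_steps, signal size) matrix per probe."""

    def __init__(self, labels, arrays):
        self.labels = list(labels)
        self.data = {lab: np.asarray(arr) for lab, arr in zip(self.labels, arrays)}

    @property
    def n_steps(self) -> int:
        return 0 if not self.labels else self.data[self.labels[0]].shape[0]

    def __getitem__(self, label) -> np.ndarray:
        return self.data[label]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {}
        for lab in self.labels:
            arr = self.data[lab]
            for i in range(arr.shape[1]):
                cols[f"{lab}[{i}]"] = arr[:, i]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def to_direct(model: Model) -> Model:
    """Replace every neuron cluster by an exact function application.

    Requires cluster metadata on the model (populated by the network
    generators).  Returns a new model sharing signals with the input; the
    member operators of each cluster are removed and one ``UserFunc`` per
    cluster is inserted at the position of the first removed operator.
    """
    if model.clusters is None:
        raise GraphError(
            "model has no cluster metadata (was it optimized before direct-"
            "mode substitution?)"
        )
    direct = Model(dt=model.dt, name=f"{model.name}:direct")
    direct.signals = list(model.signals)
    direct.probes = list(model.probes)
    direct.clusters = []
    removed: dict[int, "object"] = {}
    for cluster in model.clusters:
        first = min(cluster.ops, key=lambda op: op.index)
        for op in cluster.ops:
            removed[id(op)] = None
        sub = UserFunc(cluster.fn, cluster.output, input=cluster.input,
                       inc=cluster.inc)
        sub.index = first.index
        removed[id(first)] = sub
    for op in model.operators:
        if id(op) in removed:
            sub = removed[id(op)]
            if sub is not None:
                direct.operators.append(sub)
        else:
            direct.operators.append(op)
    direct._next_index = model._next_index
    return direct


def run(model: Model, n_steps: int, mode: str = "lif",
        state: SimulatorState | None = None) -> ProbeData:
    """Simulate ``n_steps`` steps and return the probed traces.

    ``mode="direct"`` substitutes neuron clusters by exact function
    applications before building the schedule (see :func:`to_direct`).
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if mode not in ("lif", "direct"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "direct":
        model = to_direct(model)
    plan = toposort(build_dependency_graph(model.operators))
    if state is None:
        state = SimulatorState(model)
    probe_arrays = [
        np.empty((n_steps, p.target.size), dtype=float) for p in model.probes
    ]
    probe_views = [state.resolve(p.target).reshape(-1) for p in model.probes]
    for k in range(n_steps):
        step(state, plan)
        for arr, view in zip(probe_arrays, probe_views):
            arr[k] = view
    return ProbeData([p.label for p in model.probes], probe_arrays)


def traces_equivalent(a: ProbeData, b: ProbeData, tol: float) -> bool:
    """True iff all probe traces agree elementwise within ``tol`` (max |Δ|)."""
    if set(a.labels) != set(b.labels):
        raise ValueError("probe label sets differ")
    for lab in a.labels:
        if a[lab].shape != b[lab].shape:
            raise ValueError(f"probe {lab!r}: shape mismatch "
                             f"{a[lab].shape} vs {b[lab].shape}")
        if a[lab].size and np.max(np.abs(a[lab] - b[lab])) > tol:
            return False
    return True


def max_trace_deviation(a: ProbeData, b: ProbeData) -> float:
    """Largest elementwise |Δ| over all shared probe traces."""
    dev = 0.0
    for lab in a.labels:
        if a[lab].size:
            dev = max(dev, float(np.max(np.abs(a[lab] - b[lab]))))
    return dev


def lif_rate(J: float, tau_rc: float = 0.02, tau_ref: float = 0.002) -> float:
    """Closed-form steady firing rate of a LIF neuron driven by constant J."""
    if J <= 1.0:
        return 0.0
    return 1.0 / (tau_ref + tau_rc * np.log1p(1.0 / (J - 1.0)))
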