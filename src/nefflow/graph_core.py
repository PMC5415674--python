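"""Signals, operators, and the dependency graph of a dataflow simulation.

A model is a collection of *signals* (named blocks of simulation memory) and
*operators* (computation nodes applied once per time step).  Each operator
declares, for every signal it touches, one of four access roles:

``set``
    defines the signal value at the start of the step (at most one per base),
``inc``
    adds to the signal value (any number),
``read``
    retrieves the value (any number),
``update``
    writes the final value for the next step (at most one per base).

These roles induce execution-order constraints — increments must run before
reads, reads before the update — which form a directed acyclic dependency
graph over the operators.  A topological sort of that graph yields the
per-step execution schedule.

Operators may address only part of a signal through a :class:`SignalView`,
a contiguous window into the base signal's memory given by an element offset
and a shape.  Views own no memory; dependency edges are induced through the
base wherever accessed memory regions overlap, while disjoint regions of one
base impose no mutual order.
"""

from __future__ import annotations

import heapq
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "GraphError",
    "RoleError",
    "CycleError",
    "Signal",
    "SignalView",
    "Operator",
    "Reset",
    "Copy",
    "ElementwiseInc",
    "DotInc",
    "BsrDotInc",
    "SimNeurons",
    "UserFunc",
    "TimeUpdate",
    "MERGEABLE_TAGS",
    "Model",
    "Probe",
    "Cluster",
    "first_view_base",
    "DependencyGraph",
    "ExecutionPlan",
    "build_dependency_graph",
    "toposort",
    "first_view_key",
    "base_of",
]


class GraphError(Exception):
    """Base class for model/graph construction errors."""


class RoleError(GraphError):
    """An access-role invariant was violated (e.g. two setters of one base)."""


class CycleError(GraphError):
    """The dependency graph contains a cycle."""

    def __init__(self, message: str, cycle: list | None = None):
        super().__init__(message)
        self.cycle = cycle or []


def _contiguous_strides(shape: tuple[int, ...]) -> tuple[int, ...]:
    """Row-major element strides for ``shape``."""
    strides = []
    acc = 1
    for extent in reversed(shape):
        strides.append(acc)
        acc *= extent
    return tuple(reversed(strides))


class Signal:
    """A named block of simulation memory holding a vector or matrix value.

    Parameters
    ----------
    name:
        Text label, unique within a model.
    initial:
        Initial value; defines shape and dtype unless given explicitly.
    shape, dtype:
        Used when ``initial`` is omitted (zeros are assumed).
    """

    is_view = False

    def __init__(self, name, initial=None, shape=None, dtype=np.float64):
        self.name = str(name)
        if initial is None:
            if shape is None:
                raise ValueError("either initial or shape is required")
            initial = np.zeros(shape, dtype=dtype)
        initial = np.asarray(initial, dtype=dtype)
        if shape is not None and tuple(shape) != initial.shape:
            raise ValueError(
                f"signal {name!r}: initial shape {initial.shape} != {tuple(shape)}"
            )
        if initial.ndim not in (1, 2):
            raise ValueError(f"signal {name!r}: only 1-D/2-D signals supported")
        if any(e <= 0 for e in initial.shape):
            raise ValueError(f"signal {name!r}: extents must be positive")
        self.initial = initial
        self.shape = initial.shape
        self.dtype = np.dtype(dtype)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    @property
    def base(self) -> "Signal":
        return self

    @property
    def offset(self) -> int:
        return 0

    @property
    def strides(self) -> tuple[int, ...]:
        return _contiguous_strides(self.shape)

    def view(self, offset: int, shape: tuple[int, ...]) -> "SignalView":
        return SignalView(self, offset, shape)

    def full_view(self) -> "SignalView":
        return SignalView(self, 0, self.shape)

    def __repr__(self):
        return f"Signal({self.name!r}, shape={self.shape})"


class SignalView:
    """A contiguous window into a base signal's memory.

    The view starts ``offset`` elements into the (row-major flattened) base
    block and spans ``prod(shape)`` elements.  Views allocate no memory:
    reading or writing a view reads or writes the base block.
    """

    is_view = True

    def __init__(self, base: Signal, offset: int, shape):
        if base.is_view:  # collapse view-of-view onto the base
            offset = base.offset + offset
            base = base.base
        shape = tuple(int(e) for e in (shape if isinstance(shape, (tuple, list)) else (shape,)))
        size = int(np.prod(shape))
        if offset < 0 or offset + size > base.size:
            raise ValueError(
                f"view [{offset}:{offset + size}] exceeds base {base.name!r} "
                f"of size {base.size}"
            )
        self.base = base
        self.offset = int(offset)
        self.shape = shape
        self.strides = _contiguous_strides(shape)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    @property
    def dtype(self):
        return self.base.dtype

    @property
    def name(self) -> str:
        return f"{self.base.name}[{self.offset}:{self.offset + self.size}]"

    def __repr__(self):
        return f"SignalView({self.base.name!r}, offset={self.offset}, shape={self.shape})"


def base_of(sig) -> Signal:
    """Base signal of a signal or view."""
    return sig.base


_ROLE_ORDER = ("sets", "incs", "reads", "updates")

#: Operator tags that support merging.  UserFunc wraps arbitrary user code and
#: can never be fused.
MERGEABLE_TAGS = frozenset(
    {"Reset", "Copy", "ElementwiseInc", "DotInc", "BsrDotInc", "SimNeurons", "TimeUpdate"}
)


class Operator:
    """A typed computation node declaring set/inc/read/update signal access.

    The role lists are ordered; merging relies on positional correspondence of
    role slots between operators of the same tag.  ``params`` holds
    tag-specific scalars (e.g. the Reset constant or LIF time constants);
    every signal an operator touches lives in exactly one role list.
    """

    def __init__(self, tag, sets=(), incs=(), reads=(), updates=(), params=None,
                 index=None):
        self.tag = str(tag)
        self.sets = list(sets)
        self.incs = list(incs)
        self.reads = list(reads)
        self.updates = list(updates)
        self.params = dict(params or {})
        self.index = index  # declaration order within a model

    @property
    def mergeable(self) -> bool:
        return self.tag in MERGEABLE_TAGS

    def all_signals(self) -> Iterator:
        """Signals in fixed role order: sets, incs, reads, updates."""
        for role in _ROLE_ORDER:
            yield from getattr(self, role)

    @property
    def has_view(self) -> bool:
        return any(s.is_view for s in self.all_signals())

    def role_lists(self):
        return {role: getattr(self, role) for role in _ROLE_ORDER}

    def __repr__(self):
        sigs = ", ".join(s.name for s in self.all_signals())
        return f"<{self.tag} #{self.index} ({sigs})>"


def Reset(target, value: float = 0.0) -> Operator:
    """Set ``target`` to a constant at the start of every step."""
    return Operator("Reset", sets=[target], params={"value": float(value)})


def Copy(src, dst, inc: bool = False) -> Operator:
    """Copy ``src`` into ``dst``; with ``inc=True`` add instead of overwrite."""
    if src.size != dst.size:
        raise ValueError(f"Copy: size mismatch {src.name} -> {dst.name}")
    roles = {"incs": [dst]} if inc else {"sets": [dst]}
    return Operator("Copy", reads=[src], params={"inc": bool(inc)}, **roles)


def ElementwiseInc(A, X, Y) -> Operator:
    """Y += A * X elementwise; all three share one shape."""
    if not (A.shape == X.shape == Y.shape):
        raise ValueError("ElementwiseInc: A, X, Y must share one shape")
    return Operator("ElementwiseInc", reads=[A, X], incs=[Y])


def DotInc(A, X, Y) -> Operator:
    """Y += A @ X with A an (m, n) matrix, X an n-vector, Y an m-vector."""
    if len(A.shape) != 2:
        raise ValueError("DotInc: A must be 2-D")
    m, n = A.shape
    if X.size != n or Y.size != m:
        raise ValueError(
            f"DotInc: incompatible shapes A={A.shape}, X={X.shape}, Y={Y.shape}"
        )
    return Operator("DotInc", reads=[A, X], incs=[Y])


def BsrDotInc(A, X, Y, n_blocks: int, block_shape: tuple[int, int]) -> Operator:
    """Block-diagonal product ``Y_k += A_k @ X_k`` over ``n_blocks`` blocks.

    ``A`` stores the dense blocks stacked vertically as an
    ``(n_blocks*m, n)`` array — storage is linear in the number of blocks;
    the off-diagonal zeros of the equivalent dense block-diagonal matrix are
    never materialized.
    """
    m, n = block_shape
    if A.shape != (n_blocks * m, n):
        raise ValueError("BsrDotInc: A must be the (n_blocks*m, n) block stack")
    if X.size != n_blocks * n or Y.size != n_blocks * m:
        raise ValueError("BsrDotInc: X/Y length must match block layout")
    return Operator(
        "BsrDotInc",
        reads=[A, X],
        incs=[Y],
        params={"n_blocks": int(n_blocks), "block_shape": (int(m), int(n))},
    )


def SimNeurons(J, out, voltage, refractory, tau_rc: float = 0.02,
               tau_ref: float = 0.002) -> Operator:
    """Spiking LIF population: input current ``J`` -> spike train ``out``.

    ``voltage`` and ``refractory`` are per-neuron state vectors carried across
    steps (update role).  ``tau_rc`` is the membrane time constant [s] and
    ``tau_ref`` the refractory period [s].
    """
    if tau_rc <= 0:
        raise ValueError("SimNeurons: tau_rc must be > 0")
    if tau_ref < 0:
        raise ValueError("SimNeurons: tau_ref must be >= 0")
    if not (J.size == out.size == voltage.size == refractory.size):
        raise ValueError("SimNeurons: J/out/voltage/refractory sizes must agree")
    return Operator(
        "SimNeurons",
        reads=[J],
        sets=[out],
        updates=[voltage, refractory],
        params={"tau_rc": float(tau_rc), "tau_ref": float(tau_ref)},
    )


def UserFunc(fn, output, input=None, inc: bool = False) -> Operator:
    """Apply an opaque callable each step; never merged with anything.

    With ``input`` given, computes ``fn(x)`` from the input value; otherwise
    ``fn(t)`` from the current simulation time.  ``fn`` may also be a key into
    :data:`nefflow.engine.FUNCTIONS` (required for JSON serialization).
    """
    roles = {"incs": [output]} if inc else {"sets": [output]}
    reads = [input] if input is not None else []
    return Operator("UserFunc", reads=reads, params={"fn": fn, "inc": bool(inc)},
                    **roles)


def TimeUpdate(step_sig, time_sig) -> Operator:
    """Advance the step counter and time signal once per step."""
    return Operator("TimeUpdate", updates=[step_sig, time_sig])


class Probe:
    """Record the value of a signal (or view) after every step."""

    def __init__(self, target, label: str):
        self.target = target
        self.label = str(label)

    def __repr__(self):
        return f"Probe({self.target.name!r} as {self.label!r})"


class Cluster:
    """Metadata tying a group of operators to the function they implement.

    Used for *direct mode*: the member operators (a neuron population plus its
    encode/decode stages) are replaced by a single :func:`UserFunc` applying
    ``fn`` to the value of ``input`` and writing ``output``.
    """

    def __init__(self, ops, input, output, fn, inc=True):
        self.ops = list(ops)
        self.input = input
        self.output = output
        self.fn = fn
        self.inc = bool(inc)


class Model:
    """A full simulation model: signals, operators, probes, and a timestep."""

    def __init__(self, dt: float = 0.001, name: str = "model"):
        self.dt = float(dt)
        self.name = name
        self.signals: list[Signal] = []
        self.operators: list[Operator] = []
        self.probes: list[Probe] = []
        self.clusters: list[Cluster] | None = []
        self.meta: dict = {}
        self._next_index = 0

    def add_signal(self, sig: Signal) -> Signal:
        self.signals.append(sig)
        return sig

    def signal(self, name, initial=None, shape=None, dtype=np.float64) -> Signal:
        return self.add_signal(Signal(name, initial=initial, shape=shape, dtype=dtype))

    def add_op(self, op: Operator) -> Operator:
        if op.index is None:
            op.index = self._next_index
        self._next_index = max(self._next_index, op.index) + 1
        self.operators.append(op)
        return op

    def add_probe(self, target, label=None) -> Probe:
        probe = Probe(target, label if label is not None else target.name)
        self.probes.append(probe)
        return probe

    def validate(self) -> None:
        """Check referential integrity and role invariants (raises on error)."""
        known = set(id(s) for s in self.signals)
        for op in self.operators:
            for s in op.all_signals():
                if id(base_of(s)) not in known:
                    raise GraphError(
                        f"{op!r} references unknown signal {base_of(s).name!r}"
                    )
        for probe in self.probes:
            if id(base_of(probe.target)) not in known:
                raise GraphError(f"probe target {probe.target.name!r} not in model")
        build_dependency_graph(self.operators)  # role invariants

    def __repr__(self):
        return (f"Model({self.name!r}, {len(self.signals)} signals, "
                f"{len(self.operators)} operators)")


class DependencyGraph:
    """Execution-order constraints between operators (a DAG).

    Thin wrapper over a :class:`networkx.DiGraph`; vertices are operators (or
    any hashable nodes, e.g. for synthetic reachability fixtures).
    """

    def __init__(self, vertices: Iterable = (), edges: Iterable[tuple] = ()):
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(vertices)
        self.graph.add_edges_from(edges)

    @property
    def vertices(self):
        return list(self.graph.nodes)

    def successors(self, v):
        return list(self.graph.successors(v))

    def predecessors(self, v):
        return list(self.graph.predecessors(v))

    def add_edge(self, u, v):
        self.graph.add_edge(u, v)

    def has_edge(self, u, v) -> bool:
        return self.graph.has_edge(u, v)

    @property
    def edges(self):
        return list(self.graph.edges)

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def replace(self, chain: Sequence, merged) -> None:
        """Remove ``chain`` and insert ``merged`` with the union of their edges."""
        chain_set = set(chain)
        preds = {p for v in chain for p in self.graph.predecessors(v)} - chain_set
        succs = {s for v in chain for s in self.graph.successors(v)} - chain_set
        self.graph.remove_nodes_from(chain)
        self.graph.add_node(merged)
        self.graph.add_edges_from((p, merged) for p in preds)
        self.graph.add_edges_from((merged, s) for s in succs)


class ExecutionPlan:
    """A topologically sorted operator schedule for one simulation step."""

    def __init__(self, operators: Sequence):
        self.operators = list(operators)

    def __len__(self):
        return len(self.operators)

    def __iter__(self):
        return iter(self.operators)


def build_dependency_graph(operators: Sequence[Operator]) -> DependencyGraph:
    """Derive the operator dependency graph from signal access roles.

    Wherever two operators access overlapping memory of one base signal, the
    access stages are ordered: the setter precedes incrementers,
    incrementers precede readers, and readers precede the updater (a setter
    also precedes readers directly when there are no incrementers, and so
    on).  Operators touching *disjoint* regions of a base — e.g. disjoint
    views, or the disjoint blocks the optimizer lays out inside a merged
    signal — impose no order on each other.

    Raises
    ------
    RoleError
        if two setters (or two updaters) write overlapping memory of one
        base signal.
    """
    stage_rank = {role: k for k, role in enumerate(_ROLE_ORDER)}
    # per base: (stage, start, end, op) for every access
    accesses: dict[int, list[tuple[int, int, int, Operator]]] = {}
    base_names: dict[int, str] = {}
    for op in operators:
        for role in _ROLE_ORDER:
            for s in getattr(op, role):
                b = base_of(s)
                accesses.setdefault(id(b), []).append(
                    (stage_rank[role], s.offset, s.offset + s.size, op)
                )
                base_names[id(b)] = b.name

    g = DependencyGraph(vertices=operators)
    for bid, entries in accesses.items():
        # at most one setter / updater per memory region: several operators
        # may set disjoint views of one base, but overlapping set (or
        # update) ranges are ambiguous and rejected.
        for role in ("sets", "updates"):
            rk = stage_rank[role]
            ranges = sorted((s0, s1) for st, s0, s1, _ in entries if st == rk)
            for (a0, a1), (b0, b1) in zip(ranges, ranges[1:]):
                if b0 < a1:
                    raise RoleError(
                        f"signal {base_names[bid]!r} has overlapping "
                        f"{role[:-1]}ters (at most one per memory region)"
                    )
        for i, (st_a, a0, a1, op_a) in enumerate(entries):
            for st_b, b0, b1, op_b in entries[i + 1:]:
                if st_a == st_b or op_a is op_b:
                    continue
                if a0 < b1 and b0 < a1:  # overlapping memory
                    if st_a < st_b:
                        g.add_edge(op_a, op_b)
                    else:
                        g.add_edge(op_b, op_a)
    return g


def _node_key(node, hint):
    idx = getattr(node, "index", None)
    if idx is None:
        idx = node if isinstance(node, (int, float, str)) else hint
    return (idx, hint)


def toposort(G: DependencyGraph) -> ExecutionPlan:
    """Deterministic topological sort of the dependency graph.

    Kahn's algorithm with ties broken by operator declaration index (or node
    value for non-operator graphs), so the schedule is stable across runs.

    Raises
    ------
    CycleError
        listing the operators of one cycle if the graph is not acyclic.
    """
    g = G.graph
    hints = {v: i for i, v in enumerate(g.nodes)}  # unique tie-breaker
    indegree = {v: g.in_degree(v) for v in g.nodes}
    heap = [(_node_key(v, hints[v]), v) for v in g.nodes if indegree[v] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        _, v = heapq.heappop(heap)
        order.append(v)
        for w in g.successors(v):
            indegree[w] -= 1
            if indegree[w] == 0:
                heapq.heappush(heap, (_node_key(w, hints[w]), w))
    if len(order) < g.number_of_nodes():
        remaining = [v for v in g.nodes if indegree[v] > 0]
        cycle_edges = nx.find_cycle(g.subgraph(remaining))
        cycle = [u for u, _ in cycle_edges]
        raise CycleError(
            "dependency graph contains a cycle: "
            + " -> ".join(repr(v) for v in cycle),
            cycle=cycle,
        )
    return ExecutionPlan(order)


def first_view_key(op: Operator) -> tuple[int, int]:
    """(offset, size) of the operator's first signal view, else (0, 0).

    Signals are scanned in fixed role order (sets, incs, reads, updates;
    declaration order within each role) so the notion of "first view" is
    consistent across all operators.
    """
    for s in op.all_signals():
        if s.is_view:
            return (s.offset, s.size)
    return (0, 0)


def first_view_base(op: Operator):
    """Base signal of the operator's first view, or None if it has none."""
    for s in op.all_signals():
        if s.is_view:
            return s.base
    return None
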