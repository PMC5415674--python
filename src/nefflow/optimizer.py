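"""Computation-graph optimizer: operator fusion with memory re-layout.

The optimizer rewrites a model so that groups of identical operators acting
on unrelated data become single operators acting on concatenated data.  Two
operators may merge when

1. they share a tag and the tag supports merging,
2. neither depends on the other (checked on the transitive closure of the
   dependency graph),
3. every positionally corresponding pair of role signals is mergeable —
   plain signals need equal dtype and matching off-axis extents; views must
   share a base, have equal strides and be exactly sequential in memory,
4. tag-specific extras hold (equal matrix shapes for DotInc, equal time
   constants for SimNeurons, equal constants for Reset, equal copy mode).

Merging plain signals allocates one new sequential block and replaces every
reference to the originals (anywhere in the model) by a view into it;
merging views allocates nothing and yields one encompassing view.  A chain
of DotInc operators becomes a single block-sparse ``BsrDotInc`` whose storage
is linear — not quadratic — in the number of merged operators.

Merge opportunities are found per group (same tag, same base of the first
view) by a single sorted sweep (:func:`perform_merges`), and the whole model
is processed in multiple passes that merge view-bearing operators first,
because views impose a memory order that merges of pure signals would
otherwise fix arbitrarily and thereby block (:func:`optimize`).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .graph_core import (
    BsrDotInc,
    DependencyGraph,
    GraphError,
    Model,
    Operator,
    Signal,
    SignalView,
    build_dependency_graph,
    first_view_base,
    first_view_key,
    toposort,
    _ROLE_ORDER,
)

__all__ = [
    "MergeError",
    "Reachability",
    "transitive_closure",
    "independent",
    "signals_mergeable",
    "views_mergeable",
    "can_merge",
    "merge_signals",
    "merge_view_chain",
    "merge_operators",
    "perform_merges",
    "group_operators",
    "optimize",
    "MergeRecord",
    "OptimizationReport",
]

logger = logging.getLogger(__name__)

#: heuristic tag order: these types are merged first, in this order; all
#: remaining tags follow alphabetically.
TAG_ORDER = ("ElementwiseInc", "Copy", "DotInc", "SimNeurons")


class MergeError(GraphError):
    """A merge precondition was violated."""


class Reachability:
    """Transitive-closure reachability with content-interned sets.

    ``reach(o)`` is the frozenset of operators reachable from ``o`` by a
    directed path.  Structurally equal sets are stored once (hash-interned),
    which keeps memory linear for graphs where many vertices share identical
    downstream structure — the typical shape of built NEF models.
    """

    def __init__(self):
        self._reach: dict[int, frozenset] = {}
        self._nodes: dict[int, object] = {}
        self._intern: dict[frozenset, frozenset] = {}

    def _intern_set(self, s: frozenset) -> frozenset:
        return self._intern.setdefault(s, s)

    def set_reach(self, node, reachable: frozenset) -> None:
        self._reach[id(node)] = self._intern_set(reachable)
        self._nodes[id(node)] = node

    def reach(self, node) -> frozenset:
        try:
            return self._reach[id(node)]
        except KeyError:
            raise KeyError(f"node {node!r} not in reachability index") from None

    def __contains__(self, node) -> bool:
        return id(node) in self._reach

    @property
    def n_stored_sets(self) -> int:
        """Number of distinct set instances kept alive (interning metric)."""
        return len(self._intern)

    @property
    def n_nodes(self) -> int:
        return len(self._reach)

    def merge_update(self, members: Sequence, merged) -> None:
        """Collapse ``members`` onto the single node ``merged``.

        The merged node inherits the union of the members' dependencies, so
        any node that reached some member now reaches ``merged`` and
        everything ``merged`` reaches.  Keeping the closure exact during a
        merge sweep matters: a merge can create new paths *between remaining
        operators*, and a stale closure could let a later merge form a cycle.
        """
        member_ids = frozenset(id(m) for m in members)
        member_objs = frozenset(members)
        merged_reach = frozenset().union(
            *(self._reach[id(m)] for m in members)
        ) - member_objs
        merged_reach = self._intern_set(merged_reach)
        for nid in list(self._reach):
            if nid in member_ids:
                continue
            r = self._reach[nid]
            if r & member_objs:
                self._reach[nid] = self._intern_set(
                    (r - member_objs) | {merged} | merged_reach
                )
        for mid in member_ids:
            self._reach.pop(mid, None)
            self._nodes.pop(mid, None)
        self.set_reach(merged, merged_reach)


def transitive_closure(G: DependencyGraph) -> Reachability:
    """Exact reachability for an acyclic dependency graph.

    Computed in reverse topological order: the reachable set of a vertex is
    the union of its successors and their reachable sets.  Raises
    :class:`~nefflow.graph_core.CycleError` on cyclic input.
    """
    order = toposort(G).operators  # raises CycleError on cycles
    R = Reachability()
    for v in reversed(order):
        succs = G.successors(v)
        reach = frozenset(succs).union(*(R.reach(s) for s in succs)) \
            if succs else frozenset()
        R.set_reach(v, reach)
    return R


def independent(o_i, o_j, R: Reachability) -> bool:
    """True iff neither operator depends on the other (no directed path)."""
    return o_j not in R.reach(o_i) and o_i not in R.reach(o_j)


def signals_mergeable(a, b, axis: int = 0) -> bool:
    """Can two plain (non-view) signals be concatenated along ``axis``?

    Requires equal dtypes and agreement on every extent except the
    concatenation axis.  A signal is never mergeable with itself: the merge
    replaces each input by a distinct view of the new block, which a shared
    input cannot satisfy.
    """
    if a.is_view or b.is_view:
        return False
    if a is b:
        return False
    if a.dtype != b.dtype:
        return False
    if len(a.shape) != len(b.shape) or axis >= len(a.shape):
        return False
    return all(
        ea == eb for d, (ea, eb) in enumerate(zip(a.shape, b.shape)) if d != axis
    )


def views_mergeable(a, b) -> bool:
    """Can two views be fused into one encompassing view?

    They must share a base, have equal strides, and be sequential in memory:
    the second view's offset equals the first view's offset plus its size.
    Views of different bases can never be merged.
    """
    if not (a.is_view and b.is_view):
        return False
    if a.base is not b.base:
        return False
    if a.strides != b.strides:
        return False
    return b.offset == a.offset + a.size


def _extras_ok(o_i: Operator, o_j: Operator) -> bool:
    tag = o_i.tag
    if tag == "Reset":
        return o_i.params["value"] == o_j.params["value"]
    if tag == "Copy":
        return o_i.params.get("inc", False) == o_j.params.get("inc", False)
    if tag == "DotInc":
        return o_i.reads[0].shape == o_j.reads[0].shape
    if tag == "BsrDotInc":
        return o_i.params["block_shape"] == o_j.params["block_shape"]
    if tag == "SimNeurons":
        return (o_i.params["tau_rc"] == o_j.params["tau_rc"]
                and o_i.params["tau_ref"] == o_j.params["tau_ref"])
    return True


def can_merge(o_i: Operator, o_j: Operator, R: Reachability) -> bool:
    """Evaluate all merge conditions for an (ordered) operator pair."""
    if o_i is o_j:
        return False
    if o_i.tag != o_j.tag or not o_i.mergeable:
        return False
    if not independent(o_i, o_j, R):
        return False
    for role in _ROLE_ORDER:
        si, sj = getattr(o_i, role), getattr(o_j, role)
        if len(si) != len(sj):
            return False
        for a, b in zip(si, sj):
            if a.is_view and b.is_view:
                if not views_mergeable(a, b):
                    return False
            elif not a.is_view and not b.is_view:
                if not signals_mergeable(a, b, axis=0):
                    return False
            else:  # a view paired with a plain signal cannot merge: viewed
                return False  # memory cannot be relocated
    # a plain signal occupying two slots (within or across the pair) cannot
    # be replaced by two different views of two different merged blocks
    plain = [id(s) for op in (o_i, o_j) for s in op.all_signals()
             if not s.is_view]
    if len(plain) != len(set(plain)):
        return False
    return _extras_ok(o_i, o_j)


def merge_signals(sigs: Sequence[Signal], axis: int = 0, name: str | None = None):
    """Concatenate plain signals into one new sequential memory block.

    Returns ``(merged, replacements)`` where ``replacements`` maps each input
    signal to a contiguous view of the merged block at its cumulative offset.
    Callers must rewrite *every* operator referencing the inputs with these
    views.  A single-signal input is returned as a full view of itself with
    no new allocation.
    """
    if not sigs:
        raise MergeError("merge_signals: empty input")
    if len(sigs) == 1:
        s = sigs[0]
        return s, {id(s): (s, s.full_view())}
    for a, b in zip(sigs, sigs[1:]):
        if not signals_mergeable(a, b, axis=axis):
            raise MergeError(f"signals {a.name!r} and {b.name!r} are not mergeable")
    initial = np.concatenate([s.initial for s in sigs], axis=axis)
    if name is None:
        name = "merged(" + "+".join(s.name for s in sigs) + ")"
    merged = Signal(name, initial=initial, dtype=sigs[0].dtype)
    replacements = {}
    offset = 0
    for s in sigs:
        replacements[id(s)] = (s, SignalView(merged, offset, s.shape))
        offset += s.size
    return merged, replacements


def merge_view_chain(views: Sequence[SignalView]) -> SignalView:
    """Fuse sequential views into one encompassing view (no allocation)."""
    if not views:
        raise MergeError("merge_view_chain: empty input")
    if len(views) == 1:
        return views[0]
    for a, b in zip(views, views[1:]):
        if not views_mergeable(a, b):
            raise MergeError(f"views {a!r} and {b!r} are not mergeable")
    first = views[0]
    total = sum(v.size for v in views)
    if len(first.shape) == 1:
        shape: tuple[int, ...] = (total,)
    else:
        ncols = first.shape[1]
        shape = (total // ncols, ncols)
    return SignalView(first.base, first.offset, shape)


@dataclass
class MergeRecord:
    """Bookkeeping for one merge: the replaced chain, the new operator, and
    the signal replacement map (old signal -> view into the merged block)."""

    replaced: list
    merged: Operator
    signal_replacements: dict  # id(old) -> (old, new view)

    @property
    def reduction(self) -> int:
        return len(self.replaced) - 1


def _merge_slot(slot_signals, replacements):
    if all(s.is_view for s in slot_signals):
        return merge_view_chain(slot_signals)
    if all(not s.is_view for s in slot_signals):
        merged, repl = merge_signals(slot_signals, axis=0)
        if len(slot_signals) > 1:
            replacements.update(repl)
        return merged
    raise MergeError("cannot merge a view with a plain signal in one slot")


def merge_operators(m: Sequence[Operator], model: Model | None = None) -> MergeRecord:
    """Fuse an ordered chain of ≥ 2 same-tag operators into one.

    Role signals are merged slot-wise (views by encompassing view, plain
    signals by concatenation).  A chain of ``DotInc`` operators becomes a
    single ``BsrDotInc`` whose dense blocks are the chained matrices.  When
    ``model`` is given, the rewrite is applied globally: the chain is removed,
    the merged operator inserted at the position of the first member, and all
    other operators, probes and the signal list updated for the replaced
    signals.
    """
    m = list(m)
    if len(m) < 2:
        raise MergeError("merge chains must contain at least 2 operators")
    tags = {op.tag for op in m}
    if len(tags) > 1:
        raise MergeError(f"cannot merge heterogeneous tags {sorted(tags)}")
    tag = m[0].tag

    plain = [id(s) for op in m for s in op.all_signals() if not s.is_view]
    if len(plain) != len(set(plain)):
        raise MergeError(
            "a plain signal appears in two slots of the merge chain; it "
            "cannot be replaced by two different views"
        )

    replacements: dict = {}
    merged_roles = {}
    for role in _ROLE_ORDER:
        lists = [getattr(op, role) for op in m]
        if len({len(l) for l in lists}) != 1:
            raise MergeError(f"role {role!r} arity differs within chain")
        merged_roles[role] = [
            _merge_slot([l[k] for l in lists], replacements)
            for k in range(len(lists[0]))
        ]

    if tag == "DotInc":
        blk = m[0].reads[0].shape
        A, X = merged_roles["reads"]
        (Y,) = merged_roles["incs"]
        merged = BsrDotInc(A, X, Y, n_blocks=len(m), block_shape=blk)
    elif tag == "BsrDotInc":
        blk = m[0].params["block_shape"]
        A, X = merged_roles["reads"]
        (Y,) = merged_roles["incs"]
        merged = BsrDotInc(A, X, Y,
                           n_blocks=sum(op.params["n_blocks"] for op in m),
                           block_shape=blk)
    else:
        merged = Operator(tag, params=dict(m[0].params), **merged_roles)
    merged.index = m[0].index

    record = MergeRecord(replaced=m, merged=merged,
                         signal_replacements=replacements)
    if model is not None:
        _apply_merge(model, record)
    return record


def _replace_signal(s, replacements):
    """Map a signal/view through the replacement table, rebasing views whose
    base was merged away."""
    hit = replacements.get(id(s))
    if hit is not None:
        return hit[1]
    if s.is_view:
        hit = replacements.get(id(s.base))
        if hit is not None:
            new_view = hit[1]  # contiguous view into the merged base
            return SignalView(new_view.base, new_view.offset + s.offset, s.shape)
    return s


def _apply_merge(model: Model, record: MergeRecord) -> None:
    chain_ids = {id(op) for op in record.replaced}
    repl = record.signal_replacements

    new_ops = []
    inserted = False
    first_id = id(record.replaced[0])
    for op in model.operators:
        if id(op) in chain_ids:
            if id(op) == first_id:
                new_ops.append(record.merged)
                inserted = True
            continue
        if repl:
            for role in _ROLE_ORDER:
                lst = getattr(op, role)
                for k, s in enumerate(lst):
                    lst[k] = _replace_signal(s, repl)
        new_ops.append(op)
    if not inserted:  # chain head not found in model: inconsistent call
        raise MergeError("merge chain is not part of the model")
    model.operators = new_ops

    if repl:
        removed = {sid for sid in repl}
        model.signals = [s for s in model.signals if id(s) not in removed]
        for probe in model.probes:
            probe.target = _replace_signal(probe.target, repl)
        if model.clusters:
            for cluster in model.clusters:
                cluster.input = _replace_signal(cluster.input, repl)
                cluster.output = _replace_signal(cluster.output, repl)
    new_bases = {id(hit[1].base): hit[1].base for hit in repl.values()}
    known = {id(s) for s in model.signals}
    for bid, base in new_bases.items():
        if bid not in known:
            model.signals.append(base)
            known.add(bid)

    # clusters whose members were consumed can no longer be substituted
    if model.clusters:
        model.clusters = [
            c for c in model.clusters
            if not any(id(op) in chain_ids for op in c.ops)
        ]


def _signal_fingerprint(op: Operator) -> tuple:
    return tuple(id(s) for s in op.all_signals())


def perform_merges(O: Sequence[Operator], R: Reachability,
                   model: Model | None = None,
                   blacklist: dict | None = None,
                   records: list | None = None) -> int:
    """One greedy merge sweep over a group of same-tag operators.

    The group is sorted by the offset of each operator's first signal view
    (ties by declaration index).  For each operator a chain of mergeable
    successors is grown; candidates whose first view starts before the end of
    the chain head's view are skipped, and the scan stops early once views
    stop being consecutive.  Chains of length ≥ 2 are merged; a view-bearing
    operator that merged with nothing is recorded in ``blacklist`` and
    skipped by later passes — unless one of its signals is later rewritten by
    a signal merge, which can rebase formerly incompatible views onto a
    common base and re-open the merge (the entry stores a fingerprint of the
    operator's signal identities for that purpose).  A candidate must be
    independent of *every* chain member.

    Returns the net operator-count reduction.
    """
    ops = list(O)
    if not ops:
        return 0
    if len({op.tag for op in ops}) > 1:
        raise MergeError("perform_merges requires a single-tag group")
    bases = {id(b) for b in (first_view_base(op) for op in ops) if b is not None}
    if len(bases) > 1:
        raise MergeError("first-view bases differ within the group")

    remaining = list(ops)
    # sweep-entry state: only operators that fail to merge in a *stable*
    # state (view op on entry, signals never rewritten during the sweep)
    # are provably unmergeable in later passes
    entry_prints = {id(op): _signal_fingerprint(op) for op in remaining}
    entry_view = {id(op): op.has_view for op in remaining}
    reduced = 0
    while True:
        order = sorted(remaining,
                       key=lambda op: (first_view_key(op)[0], op.index))
        prints = {id(op): _signal_fingerprint(op) for op in order}
        consumed: set[int] = set()
        unmerged: list[Operator] = []
        restart = False
        for i, o_i in enumerate(order):
            if id(o_i) in consumed:
                continue
            off_i, size_i = first_view_key(o_i)
            m = [o_i]
            m_plain = {id(s) for s in o_i.all_signals() if not s.is_view}
            for o_j in order[i + 1:]:
                if id(o_j) in consumed:
                    continue
                off_j, _ = first_view_key(o_j)
                if off_j < off_i + size_i:
                    continue  # o_j's view starts inside o_i's: skip
                last = m[-1]
                j_plain = {id(s) for s in o_j.all_signals() if not s.is_view}
                if can_merge(last, o_j, R) and not (m_plain & j_plain) and all(
                    independent(x, o_j, R) for x in m[:-1]
                ):
                    m.append(o_j)
                    m_plain |= j_plain
                else:
                    off_l, size_l = first_view_key(last)
                    if off_l + size_l < off_j:
                        break  # views not consecutive: nothing further fits
            if len(m) > 1:
                record = merge_operators(m, model)
                if model is not None:
                    # refresh the exact closure from the rewritten graph:
                    # the union rule (DependencyGraph.replace) is a sound
                    # but strict over-approximation, and a spurious
                    # dependence would block (and blacklist) legal merges
                    R = transitive_closure(
                        build_dependency_graph(model.operators))
                else:
                    R.merge_update(m, record.merged)
                consumed.update(id(op) for op in m)
                reduced += record.reduction
                if records is not None:
                    records.append(record)
                # a merge may rewrite signals of *other group members* (a
                # shared signal merged into a new base); their sort offsets
                # are then stale, so restart the sweep over the remainder
                remaining = [op for op in remaining
                             if id(op) not in consumed]
                if any(_signal_fingerprint(op) != prints[id(op)]
                       for op in remaining):
                    restart = True
                    break
            else:
                unmerged.append(o_i)
        if restart:
            continue
        if blacklist is not None:
            for op in unmerged:
                if entry_view[id(op)] and \
                        _signal_fingerprint(op) == entry_prints[id(op)]:
                    blacklist[id(op)] = entry_prints[id(op)]
        return reduced


def group_operators(ops: Sequence[Operator]) -> list[list[Operator]]:
    """Group operators by (tag, base of first view) in heuristic tag order.

    Operators without views form one group per tag.  Within a tag, groups are
    emitted in order of first appearance; tags outside the heuristic prefix
    (ElementwiseInc, Copy, DotInc, SimNeurons) follow alphabetically.
    """
    groups: dict[tuple, list[Operator]] = {}
    for op in ops:
        base = first_view_base(op)
        key = (op.tag, id(base) if base is not None else None)
        groups.setdefault(key, []).append(op)

    rank = {tag: r for r, tag in enumerate(TAG_ORDER)}

    def tag_rank(tag: str):
        return (rank[tag], "") if tag in rank else (len(rank), tag)

    seen_order = {key: i for i, key in enumerate(groups)}
    ordered = sorted(groups, key=lambda key: (tag_rank(key[0]), seen_order[key]))
    return [groups[key] for key in ordered]


@dataclass
class PassRecord:
    view_pass: bool
    merges: int
    duration: float


@dataclass
class OptimizationReport:
    ops_before: int = 0
    ops_after: int = 0
    passes: list = field(default_factory=list)
    signal_replacement_count: int = 0

    @property
    def total_merged(self) -> int:
        return sum(p.merges for p in self.passes)

    def to_dict(self) -> dict:
        return {
            "ops_before": self.ops_before,
            "ops_after": self.ops_after,
            "signal_replacement_count": self.signal_replacement_count,
            "passes": [
                {"view_pass": p.view_pass, "merges": p.merges,
                 "duration": p.duration}
                for p in self.passes
            ],
        }


def optimize(model: Model,
             clock: Callable[[], float] = time.monotonic,
             enable_rate_stop: bool = False,
             rate_threshold: float = 0.01) -> tuple[Model, OptimizationReport]:
    """Optimize a model's computation graph by operator and signal merging.

    Runs repeated merge passes until the operator count stops shrinking.
    Passes alternate on the ``v`` flag: while reductions continue, only
    view-bearing operators are considered (views impose a memory order that
    merging pure signals first could contradict — merging view operators
    first propagates that order outward); after a pass without reduction, one
    pass over view-free operators runs.  With ``enable_rate_stop``, the loop
    additionally stops once the per-pass merge rate falls below
    ``rate_threshold`` of the average rate over all passes, which bounds the
    optimization time for very large models.

    The input model is left untouched; the returned model is a rewritten
    deep copy, together with a report of per-pass merge counts.
    """
    import copy

    work = copy.deepcopy(model)
    report = OptimizationReport(ops_before=len(work.operators))
    blacklist: dict[int, tuple] = {}
    records: list[MergeRecord] = []

    n_all = len(work.operators)
    n_0, n_1 = n_all, 0
    t_start = clock()
    t_pass = t_start
    v = True if n_all else False

    def rate_ok(now: float) -> bool:
        if not enable_rate_stop:
            return True
        total_elapsed = now - t_start
        pass_elapsed = now - t_pass
        avg = rate_threshold * n_all / total_elapsed if total_elapsed > 0 \
            else 0.0
        cur = (n_0 - n_1) / pass_elapsed if pass_elapsed > 0 else float("inf")
        return avg < cur

    while v or (n_1 < n_0 and rate_ok(clock())):
        t_pass = clock()
        v = n_0 != n_1
        alive = {id(op) for op in work.operators}
        candidates = [
            op for op in work.operators
            if op.has_view == v and op.mergeable
            and blacklist.get(id(op)) != _signal_fingerprint(op)
        ]
        n_0 = len(work.operators)
        merges = 0
        for group in group_operators(candidates):
            group = [op for op in group if id(op) in alive]
            if not group:
                continue
            # rewrites earlier in this pass may have rebased first views, so
            # re-split the group on the current (tag, base) key
            for subgroup in group_operators(group):
                G = build_dependency_graph(work.operators)
                R = transitive_closure(G)
                merges += perform_merges(subgroup, R, model=work,
                                         blacklist=blacklist, records=records)
                alive = {id(op) for op in work.operators}
        n_1 = len(work.operators)
        duration = clock() - t_pass
        report.passes.append(PassRecord(view_pass=v, merges=merges,
                                        duration=duration))
        logger.info("pass %d (views=%s): %d merges, %d -> %d operators",
                    len(report.passes), v, merges, n_0, n_1)

    report.ops_after = len(work.operators)
    report.signal_replacement_count = sum(
        len(r.signal_replacements) for r in records
    )
    return work, report
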