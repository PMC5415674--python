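"""Operator fusion: merge conditions, the sweep, the pass loop."""

import numpy as np
import networkx as nx
import pytest

from nefflow.engine import SimulatorState, run, step, traces_equivalent
from nefflow.graph_core import (
    Copy,
    DotInc,
    ElementwiseInc,
    Model,
    Reset,
    Signal,
    SignalView,
    UserFunc,
    build_dependency_graph,
    toposort,
)
from nefflow.netgen import fig3_fixture, gen_random_dag, gen_random_model
from nefflow.optimizer import (
    MergeError,
    can_merge,
    group_operators,
    independent,
    merge_operators,
    merge_signals,
    merge_view_chain,
    optimize,
    perform_merges,
    signals_mergeable,
    transitive_closure,
    views_mergeable,
)
from conftest import two_population_model


def closure_of(ops):
    return transitive_closure(build_dependency_graph(ops))


class TestTransitiveClosure:
    def test_chain(self):
        g = gen_random_dag(3, 0.0)
        g.add_edge(0, 1)
        g.add_edge(1, 2)
        R = transitive_closure(g)
        assert R.reach(0) == {1, 2}
        assert R.reach(1) == {2}
        assert R.reach(2) == frozenset()

    def test_parallel_sources_share_one_interned_set(self):
        g = gen_random_dag(11, 0.0)
        for src in range(10):
            g.add_edge(src, 10)
        R = transitive_closure(g)
        sets = {id(R.reach(src)) for src in range(10)}
        assert len(sets) == 1  # one stored instance for all ten sources
        assert R.reach(0) == {10}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_vertex_bfs(self, seed):
        g = gen_random_dag(120, 0.05, seed=seed)
        R = transitive_closure(g)
        for v in g.vertices:
            assert R.reach(v) == nx.descendants(g.graph, v)

    def test_interned_set_count_scales_with_chain_not_vertices(self):
        # k sources feeding one chain of length L: L+1 distinct sets total
        k, L = 50, 5
        g = gen_random_dag(k + L, 0.0)
        chain = list(range(k, k + L))
        for a, b in zip(chain, chain[1:]):
            g.add_edge(a, b)
        for src in range(k):
            g.add_edge(src, chain[0])
        R = transitive_closure(g)
        assert R.n_stored_sets == L + 1
        assert R.n_stored_sets < k + L

    def test_cycle_rejected(self):
        from nefflow.graph_core import CycleError, DependencyGraph

        g = DependencyGraph(vertices=[0, 1], edges=[(0, 1), (1, 0)])
        with pytest.raises(CycleError):
            transitive_closure(g)

    def test_merge_update_union_semantics(self):
        g = gen_random_dag(4, 0.0)
        g.add_edge(0, 1)
        g.add_edge(2, 3)
        R = transitive_closure(g)
        R.merge_update([1, 2], "M")
        assert "M" in R.reach(0)
        assert 3 in R.reach(0)  # 0 -> M -> 3 through the union
        assert R.reach("M") == {3}


class TestIndependence:
    def test_dependent_cluster_pair(self):
        m = Model()
        src = m.signal("src", initial=[1.0])
        mid = m.signal("mid", shape=(1,))
        A = m.signal("A", initial=[[2.0]])
        y = m.signal("y", shape=(1,))
        c = m.add_op(Copy(src, mid))
        m.add_op(Reset(y))
        d = m.add_op(DotInc(A, mid, y))
        R = closure_of(m.operators)
        assert not independent(c, d, R)

    def test_disjoint_components_independent(self):
        a = Copy(Signal("a", initial=[1.0]), Signal("b", shape=(1,)))
        b = Copy(Signal("c", initial=[1.0]), Signal("d", shape=(1,)))
        assert independent(a, b, closure_of([a, b]))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_path_existence(self, seed):
        g = gen_random_dag(40, 0.1, seed=seed)
        R = transitive_closure(g)
        rng = np.random.default_rng(seed)
        for _ in range(50):
            u, v = rng.integers(0, 40, size=2)
            if u == v:
                continue
            expected = not (nx.has_path(g.graph, int(u), int(v))
                            or nx.has_path(g.graph, int(v), int(u)))
            assert independent(int(u), int(v), R) == expected


class TestSignalsMergeable:
    def test_vectors_always_agree_off_axis(self):
        assert signals_mergeable(Signal("a", shape=(4,)), Signal("b", shape=(7,)))

    def test_matrix_shapes_agree_except_concat_axis(self):
        assert signals_mergeable(Signal("a", shape=(3, 4)),
                                 Signal("b", shape=(5, 4)), axis=0)
        assert not signals_mergeable(Signal("a", shape=(3, 4)),
                                     Signal("b", shape=(3, 5)), axis=0)

    def test_dtype_must_match(self):
        a = Signal("a", shape=(3,), dtype=np.float64)
        b = Signal("b", shape=(3,), dtype=np.float32)
        assert not signals_mergeable(a, b)

    def test_signal_never_merges_with_itself(self):
        s = Signal("s", shape=(3,))
        assert not signals_mergeable(s, s)


class TestViewsMergeable:
    def setup_method(self):
        self.base = Signal("base", shape=(16,))

    def test_sequential_views_merge(self):
        a = SignalView(self.base, 0, (4,))
        b = SignalView(self.base, 4, (4,))
        assert views_mergeable(a, b)
        assert not views_mergeable(b, a)

    def test_gap_blocks_merge(self):
        assert not views_mergeable(SignalView(self.base, 0, (4,)),
                                   SignalView(self.base, 5, (4,)))

    def test_different_bases_never_merge(self):
        other = Signal("other", shape=(16,))
        assert not views_mergeable(SignalView(self.base, 0, (4,)),
                                   SignalView(other, 4, (4,)))

    def test_stride_mismatch_blocks_merge(self):
        a = SignalView(Signal("m", shape=(4, 4)), 0, (2, 4))
        b = SignalView(a.base, 8, (4, 2))
        assert not views_mergeable(a, b)


class TestCanMerge:
    def test_same_shape_dot_incs_merge(self, rng):
        ops = []
        for i in range(2):
            A = Signal(f"A{i}", initial=rng.standard_normal((2, 2)))
            x = Signal(f"x{i}", initial=rng.standard_normal(2))
            y = Signal(f"y{i}", shape=(2,))
            ops.append(Reset(y))
            ops.append(DotInc(A, x, y))
        R = closure_of(ops)
        assert can_merge(ops[1], ops[3], R)

    def test_tag_mismatch(self):
        c = Copy(Signal("a", initial=[1.0]), Signal("b", shape=(1,)))
        y = Signal("y", shape=(1,))
        d = DotInc(Signal("A", initial=[[1.0]]), Signal("x", initial=[1.0]), y)
        ops = [c, Reset(y), d]
        assert not can_merge(c, d, closure_of(ops))

    def test_user_funcs_never_merge(self):
        u1 = UserFunc(lambda t: [t], Signal("o1", shape=(1,)))
        u2 = UserFunc(lambda t: [t], Signal("o2", shape=(1,)))
        assert not can_merge(u1, u2, closure_of([u1, u2]))

    def test_view_paired_with_plain_signal_fails(self):
        base = Signal("base", shape=(4,))
        c1 = Copy(Signal("s1", initial=[1.0, 1.0]), SignalView(base, 0, (2,)))
        c2 = Copy(Signal("s2", initial=[1.0]), Signal("d", shape=(1,)))
        assert not can_merge(c1, c2, closure_of([c1, c2]))

    def test_differing_reset_values_fail(self):
        r1, r2 = Reset(Signal("a", shape=(1,)), 0.0), Reset(Signal("b", shape=(1,)), 1.0)
        assert not can_merge(r1, r2, closure_of([r1, r2]))

    def test_shared_plain_signal_fails(self):
        src = Signal("shared", initial=[1.0])
        c1 = Copy(src, Signal("d1", shape=(1,)))
        c2 = Copy(src, Signal("d2", shape=(1,)))
        assert not can_merge(c1, c2, closure_of([c1, c2]))


class TestMergeSignals:
    def test_concatenation_with_offsets(self):
        a = Signal("a", initial=[1.0, 2.0])
        b = Signal("b", initial=[3.0, 4.0, 5.0])
        merged, repl = merge_signals([a, b])
        assert np.allclose(merged.initial, [1, 2, 3, 4, 5])
        assert repl[id(a)][1].offset == 0
        assert repl[id(b)][1].offset == 2

    def test_single_signal_full_view(self):
        a = Signal("a", initial=[1.0, 2.0])
        merged, repl = merge_signals([a])
        assert merged is a
        view = repl[id(a)][1]
        assert view.base is a and view.offset == 0 and view.size == 2

    def test_round_trip_through_views(self, rng):
        sigs = [Signal(f"s{i}", initial=rng.standard_normal(rng.integers(1, 6)))
                for i in range(5)]
        merged, repl = merge_signals(sigs)
        flat = merged.initial
        for s in sigs:
            v = repl[id(s)][1]
            assert np.array_equal(flat[v.offset:v.offset + v.size], s.initial)

    def test_unmergeable_rejected(self):
        a = Signal("a", shape=(2, 2))
        b = Signal("b", shape=(2, 3))
        with pytest.raises(MergeError):
            merge_signals([a, b])


class TestMergeViewChain:
    def test_two_views(self):
        base = Signal("base", shape=(8,))
        v = merge_view_chain([SignalView(base, 0, (4,)),
                              SignalView(base, 4, (4,))])
        assert (v.offset, v.size) == (0, 8)

    def test_single_view_identity(self):
        base = Signal("base", shape=(8,))
        a = SignalView(base, 2, (3,))
        assert merge_view_chain([a]) is a

    def test_unit_views_alias_same_buffer(self):
        m = Model()
        base = m.signal("base", initial=np.arange(6.0))
        views = [SignalView(base, k, (1,)) for k in range(2, 5)]
        merged = merge_view_chain(views)
        state = SimulatorState(m)
        assert np.array_equal(state.resolve(merged), [2.0, 3.0, 4.0])
        state.resolve(merged)[0] = -1.0
        assert state.resolve(base)[2] == -1.0

    def test_gap_rejected(self):
        base = Signal("base", shape=(8,))
        with pytest.raises(MergeError):
            merge_view_chain([SignalView(base, 0, (2,)),
                              SignalView(base, 3, (2,))])


class TestMergeOperators:
    def test_two_copies_execute_identically(self, rng):
        def build():
            m = Model()
            ops = []
            for i in range(2):
                src = m.signal(f"src{i}", initial=rng.standard_normal(3))
                dst = m.signal(f"dst{i}", shape=(3,))
                ops.append(m.add_op(Copy(src, dst)))
                m.add_probe(dst, f"dst{i}")
            return m, ops

        rng = np.random.default_rng(5)
        plain, _ = build()
        rng = np.random.default_rng(5)
        merged_model, ops = build()
        record = merge_operators(ops, merged_model)
        assert record.merged.tag == "Copy"
        assert len(merged_model.operators) == 1
        assert traces_equivalent(run(plain, 1), run(merged_model, 1), tol=0.0)

    def test_chain_of_one_rejected(self):
        c = Copy(Signal("a", initial=[1.0]), Signal("b", shape=(1,)))
        with pytest.raises(MergeError):
            merge_operators([c])

    def test_heterogeneous_tags_rejected(self):
        y = Signal("y", shape=(1,))
        c = Copy(Signal("a", initial=[1.0]), Signal("b", shape=(1,)))
        r = Reset(y)
        with pytest.raises(MergeError):
            merge_operators([c, r])

    def test_dot_inc_chain_becomes_bsr(self, rng):
        m = Model()
        mats, xs = [], []
        ops = []
        for i in range(2):
            A0 = rng.standard_normal((2, 2))
            x0 = rng.standard_normal(2)
            mats.append(A0)
            xs.append(x0)
            A = m.signal(f"A{i}", initial=A0)
            x = m.signal(f"x{i}", initial=x0)
            y = m.signal(f"y{i}", shape=(2,))
            m.add_op(Reset(y))
            ops.append(m.add_op(DotInc(A, x, y)))
            m.add_probe(y, f"y{i}")
        record = merge_operators(ops, m)
        assert record.merged.tag == "BsrDotInc"
        assert record.merged.params["n_blocks"] == 2
        data = run(m, 1)
        # dense block-diagonal oracle
        for i in range(2):
            assert np.allclose(data[f"y{i}"][0], mats[i] @ xs[i], atol=1e-12)

    def test_duplicate_signal_across_chain_rejected(self):
        shared = Signal("shared", initial=[1.0])
        m = Model()
        m.add_signal(shared)
        d1 = m.signal("d1", shape=(1,))
        d2 = m.signal("d2", shape=(1,))
        c1 = m.add_op(Copy(shared, d1))
        c2 = m.add_op(Copy(shared, d2))
        with pytest.raises(MergeError):
            merge_operators([c1, c2], m)


def sweep(model, group):
    R = closure_of(model.operators)
    return perform_merges(group, R, model=model)


class TestPerformMerges:
    def consecutive_view_copies(self, offsets, sizes):
        m = Model()
        base = m.signal("base", shape=(sum(sizes) + max(offsets), ))
        m.add_op(Reset(base))
        ops = []
        for k, (off, size) in enumerate(zip(offsets, sizes)):
            src = m.signal(f"src{k}", initial=np.ones(size))
            ops.append(m.add_op(Copy(src, SignalView(base, off, (size,)),
                                     inc=True)))
        return m, ops

    def test_four_consecutive_views_one_chain(self):
        m, ops = self.consecutive_view_copies([0, 2, 4, 6], [2, 2, 2, 2])
        assert sweep(m, ops) == 3
        assert len([o for o in m.operators if o.tag == "Copy"]) == 1

    def test_gap_blocks_merge(self):
        m, ops = self.consecutive_view_copies([0, 3], [2, 2])
        assert sweep(m, ops) == 0

    def test_view_free_group_fully_merges(self, rng):
        m = Model()
        ops = []
        for i in range(10):
            L = 3
            A = m.signal(f"A{i}", initial=rng.standard_normal(L))
            X = m.signal(f"X{i}", initial=rng.standard_normal(L))
            Y = m.signal(f"Y{i}", shape=(L,))
            m.add_op(Reset(Y))
            ops.append(m.add_op(ElementwiseInc(A, X, Y)))
        assert sweep(m, ops) == 9
        assert len([o for o in m.operators if o.tag == "ElementwiseInc"]) == 1

    @pytest.mark.parametrize("n", [2, 3, 6])
    def test_independent_ops_collapse_like_exhaustive_pairwise(self, n, rng):
        # oracle: for n pairwise-mergeable independent operators, exhaustive
        # pairwise merging always terminates with a single operator
        m = Model()
        ops = []
        for i in range(n):
            A = m.signal(f"A{i}", initial=rng.standard_normal(2))
            X = m.signal(f"X{i}", initial=rng.standard_normal(2))
            Y = m.signal(f"Y{i}", shape=(2,))
            m.add_op(Reset(Y))
            ops.append(m.add_op(ElementwiseInc(A, X, Y)))
        assert sweep(m, ops) == n - 1

    def test_mixed_tags_rejected(self):
        c = Copy(Signal("a", initial=[1.0]), Signal("b", shape=(1,)))
        y = Signal("y", shape=(1,))
        r = Reset(y)
        with pytest.raises(MergeError):
            perform_merges([c, r], closure_of([c, r]))


class TestGroupOperators:
    def test_heuristic_tag_order(self, rng):
        y1 = Signal("y1", shape=(2,))
        y2 = Signal("y2", shape=(2,))
        ops = [
            DotInc(Signal("A", initial=rng.standard_normal((2, 2))),
                   Signal("x", initial=rng.standard_normal(2)), y1),
            Copy(Signal("c", initial=[1.0, 1.0]), y2),
        ]
        groups = group_operators(ops)
        assert [g[0].tag for g in groups] == ["Copy", "DotInc"]

    def test_different_first_view_bases_split(self, rng):
        b1 = Signal("b1", shape=(4,))
        b2 = Signal("b2", shape=(4,))
        y1, y2 = Signal("y1", shape=(2,)), Signal("y2", shape=(2,))
        ops = [
            DotInc(Signal("A1", initial=rng.standard_normal((2, 2))),
                   SignalView(b1, 0, (2,)), y1),
            DotInc(Signal("A2", initial=rng.standard_normal((2, 2))),
                   SignalView(b2, 0, (2,)), y2),
        ]
        assert len(group_operators(ops)) == 2

    def test_empty_input(self):
        assert group_operators([]) == []


class TestOptimize:
    def test_two_population_model_merges_per_tag(self, two_pop_model):
        opt, report = optimize(two_pop_model)
        tags = sorted(op.tag for op in opt.operators)
        # one operator per cluster stage; DotIncs became one BsrDotInc
        assert tags.count("SimNeurons") == 1
        assert tags.count("BsrDotInc") == 1
        assert tags.count("ElementwiseInc") == 1
        assert report.ops_after == len(opt.operators)
        assert report.ops_before - report.total_merged == report.ops_after

    def test_preserves_traces(self, two_pop_model):
        opt, _ = optimize(two_pop_model)
        assert traces_equivalent(run(two_pop_model, 100), run(opt, 100),
                                 tol=1e-9)

    def test_fixed_point(self, two_pop_model):
        opt, _ = optimize(two_pop_model)
        opt2, report2 = optimize(opt)
        assert report2.total_merged == 0
        assert len(opt2.operators) == len(opt.operators)

    def test_monotone_and_graph_valid_after_optimize(self):
        for seed in range(5):
            m = gen_random_model(25, seed=seed)
            opt, report = optimize(m)
            assert report.ops_after <= report.ops_before
            assert all(p.merges >= 0 for p in report.passes)
            toposort(build_dependency_graph(opt.operators))  # acyclic
            opt.validate()

    def test_input_model_untouched(self, two_pop_model):
        before = [(op.tag, [s.name for s in op.all_signals()])
                  for op in two_pop_model.operators]
        optimize(two_pop_model)
        after = [(op.tag, [s.name for s in op.all_signals()])
                 for op in two_pop_model.operators]
        assert before == after

    def test_empty_model(self):
        opt, report = optimize(Model())
        assert report.ops_before == report.ops_after == 0
        assert report.passes == []

    def test_fig3_view_first_merges_everything(self):
        opt, _ = optimize(fig3_fixture())
        assert len(opt.operators) == 2

    def test_fig3_adverse_order_blocks_o1(self):
        m = fig3_fixture()
        o2a, o2b = m.operators[2], m.operators[3]
        merge_operators([o2b, o2a], m)  # adversarial (b2, b1) memory order
        opt, _ = optimize(m)
        assert len(opt.operators) >= 3

    def test_fake_clock_rate_stop_terminates(self, two_pop_model):
        ticks = iter(np.arange(0.0, 1000.0, 0.5))
        opt, report = optimize(two_pop_model, clock=lambda: next(ticks),
                               enable_rate_stop=True)
        assert report.ops_after <= report.ops_before
        opt_ref, _ = optimize(two_pop_model, enable_rate_stop=False)
        # with a well-behaved clock the rate stop changes nothing here
        assert len(opt.operators) == len(opt_ref.operators)

    def test_report_serializes(self, two_pop_model):
        import json

        _, report = optimize(two_pop_model)
        payload = json.loads(json.dumps(report.to_dict()))
        assert payload["ops_before"] >= payload["ops_after"]
        assert len(payload["passes"]) == len(report.passes)
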