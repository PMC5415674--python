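# Methods

## The dataflow model

A model is a set of **signals** — named 1-D/2-D float64 blocks of simulation
memory with initial values — and **operators**, each applied once per time
step.  Operators declare one of four access roles per signal: at most one
*set* (defines the value at the start of the step) and at most one *update*
(writes the value for the next step) per memory region, and any number of
*increments* and *reads*.  A **view** addresses a contiguous window of a base
signal (0-based element offset, row-major, element strides); views own no
memory.

Dependency edges are derived from the roles wherever two operators access
**overlapping memory** of one base: set → inc → read → update (each stage
precedes every later non-empty stage).  Operators touching disjoint regions
of a base impose no order on each other.  This region-level granularity is
not an optimization but a correctness requirement: the optimizer concatenates
unrelated signals into a common base, and ordering by base identity alone
would manufacture false dependencies — including cycles — between the
regions' operators.  Overlapping set (or update) ranges are rejected.

The schedule is a deterministic topological sort (Kahn's algorithm; ties
broken by operator declaration index), so identical models always produce
identical schedules and, since every operator is deterministic, identical
simulations.

Operator inventory: `Reset` (constant fill), `Copy` (overwrite or add),
`ElementwiseInc` (`Y += A∘X`), `DotInc` (`Y += A·X`), `BsrDotInc` (the merged
block-diagonal product), `SimNeurons` (spiking LIF), `UserFunc` (arbitrary
callable of time or of an input signal; never merged), `TimeUpdate`.

## Optimizer

Two operators merge when (1) tags match and the tag supports merging,
(2) neither reaches the other in the transitive closure of the dependency
graph, (3) each positionally corresponding signal pair is mergeable — plain
signals: same dtype, equal extents off the concatenation axis, not the same
object; views: same base, equal strides, second offset = first offset +
first size — and (4) tag extras hold (equal matrix shapes for `DotInc`,
equal `tau_rc`/`tau_ref` for `SimNeurons`, equal constants for `Reset`,
equal copy mode).  A chain merges when every adjacent pair does; we
additionally require each candidate to be independent of **every** chain
member and require that no plain signal occupies two slots anywhere in the
chain (pairwise checks alone admit a shared source two positions apart,
which cannot be expressed by the one-to-one signal replacement map).

Merging plain signals allocates one concatenated block and rewrites every
reference model-wide (references to merged-away bases are rebased, probes
included); merging views creates one encompassing view and allocates
nothing.  A `DotInc` chain becomes one `BsrDotInc` whose dense blocks are
the chained matrices in order — storage is Σ per-block m·n, linear in the
chain length, never the quadratic dense block-diagonal.

**Finding chains.**  Operators are grouped by (tag, base of the first view;
view-free operators form one group per tag), ordered ElementwiseInc, Copy,
DotInc, SimNeurons, then remaining tags alphabetically.  Within a group, a
single sweep over the operators sorted by first-view offset grows greedy
chains; candidates whose view starts before the end of the head's view are
skipped, and the scan stops once views are no longer consecutive.  View
operators that fail to merge while in a *stable* state (view-bearing at
sweep entry, signals untouched throughout the sweep) can never merge later
and are excluded from future passes; the exclusion is keyed to a fingerprint
of the operator's signal identities and lapses automatically if a later
signal merge rewrites them — rebasing two views onto a common base can
re-open a merge.  If a merge rewrites the signals of other operators in the
same group (they shared a merged signal), the sweep restarts over the
remainder with fresh offsets.

**Pass loop.**  Passes alternate on a view flag `v`: while reductions
continue only view-bearing operators are considered, because views impose a
memory order that merging order-free plain signals first can contradict and
permanently block (the four-operator fixture `fig3_fixture` demonstrates
both outcomes); after a pass without reduction one pass over view-free
operators runs.  Optionally the loop also stops when a pass's merges-per-
second falls below 1% of the average over all passes — a guard for
very large builds that is off by default in the library (it depends on
wall-clock time; tests inject a fake clock) and available as `--rate-stop`
in the CLI.  A pass that takes no measurable time is treated as infinitely
fast rather than dividing by zero.

**Reachability.**  Dependence queries use the transitive closure, computed
in reverse topological order with hash-interned frozensets so that vertices
with identical reachable sets share one stored instance (typical NEF graphs
have many such vertices; on k parallel sources feeding a chain of length L
the store holds L+1 sets, not k+L).  During a sweep the closure is
recomputed from the rewritten graph after every merge: updating it by the
union-of-dependencies rule is sound but over-approximates the rebuilt
graph's dependences, and a spurious dependence would both block a legal
merge and poison the exclusion list.  At desk scale (≤ ~1,000 operators)
the recomputation is cheap; `Reachability.merge_update` retains the union
semantics for standalone graph surgery.

The optimizer works on a deep copy; the input model is never mutated.
Reports carry per-pass merge counts and durations, operator counts before
and after, and the number of signal replacements.

## Engine

Buffers exist per base signal; views resolve to numpy views of the base
buffer.  Each operator is compiled once per plan into a closure over its
resolved arrays, so the per-step cost is one Python call plus vectorized
numpy per operator — which is exactly why fewer, larger operators simulate
faster.  `BsrDotInc` applies one matrix–vector product per block (the same
BLAS call, on the same elements, as the unmerged `DotInc`s), so optimized
and unoptimized runs agree bit-for-bit rather than merely to rounding;
`ElementwiseInc`, `Copy`, `Reset` and `SimNeurons` are elementwise and
identical by construction.

**LIF neurons.**  `tau_rc · dv/dt = J − v` with exact exponential
integration per step, threshold 1, reset to 0, spike amplitude `1/dt`,
refractory period `tau_ref`.  Defaults `tau_rc = 0.02 s`, `tau_ref =
0.002 s`, `dt = 0.001 s` (the standard NEF parameterization).  The
threshold-crossing time within a step is interpolated and carried into the
refractory hold; without it, rate quantization at dt = 1 ms reaches ~8%
error at J = 5, while with it the simulated rate matches the closed form
`1/(tau_ref + tau_rc·ln(1 + 1/(J−1)))` to well under 1%.  Non-finite input
currents raise.

**Direct mode** replaces each neuron cluster (current reset, encode, gain/
bias, nonlinearity, decode) by a single `UserFunc` applying the represented
function exactly.  Substitution happens on the un-optimized model using
cluster metadata recorded by the generators; optimization consumes that
metadata for merged clusters, so `to_direct` after optimizing raises rather
than silently mis-simulating.  Optimize-the-direct-model is the supported
composition.

## Synthetic networks

The generators emit the operator/signal structure of built NEF models —
many small populations, each a Reset/Copy/DotInc/ElementwiseInc/SimNeurons
cluster, with view-sliced routing through shared vectors — so the optimizer
is exercised end-to-end without an external builder.

*Circular convolution* (`u_i = Σ_j v_j·w_{(i−j) mod n}`, the binding
operation of vector-symbolic cognitive models): realized spectrally with
real matrices A, B (p×d) and C (d×p) such that `C·((Av)∘(Bw)) = v⊛w`, using
the half-spectrum DFT and the three-multiplication complex product, giving
`p = 3·(d//2+1) ≤ 2d+2` scalar products, each computed by one two-input
population.  The raw operator count is `9p + 5` — affine in d over even d
(the half-spectrum fold makes odd/even intercepts differ) — while the
optimized count is d-independent; d ∈ {4, 16, 64} at 4 neurons per
dimension is the exercised range, a deliberate desk-scale stand-in for
500-neuron-per-dimension builds, since merge behaviour depends on graph
structure, not on population size.  Inputs are seeded unit vectors.

*Split ensembles*: a d-vector represented by s groups of d/s dimensions,
routed through views of shared input/output signals — the structure whose
operator count grows with s and which the optimizer collapses back to a
near-constant.  Direct mode implements the identity, so the probe must
reproduce the input exactly.

Encoders and decoders are **seeded Gaussian matrices, not least-squares NEF
decoders**: optimizer correctness is weight-independent, and trace
equivalence is asserted bit-for-bit against the unoptimized run, so solving
for decoders would add cost without adding evidence.  Consequently the LIF
circconv network does not *approximate* the convolution (only direct mode
is compared with the oracle), and passing tests say nothing about
representational accuracy of real trained networks — only about graph
semantics, which is the property the optimizer must preserve.  Gains and
biases are drawn Uniform(0.5, 1.5) so populations actually spike at the
simulated operating point.

*Random models* (fuzzing surface): seeded operator soup satisfying every
role invariant by construction — signals are only read after all their
incrementers exist, so edges always point from earlier- to later-created
operators and the graph is acyclic; incremented signals always carry a Reset
setter; all written signals are probed, making the equivalence check
exhaustive.  Random DAGs for reachability tests use ordered-pair coin flips
(edges only low→high index).

## Benchmark harness

Per trial: timed build (including optimization when enabled), 10 untimed
warm-up steps, 1,000 timed steps; means over five trials by default.
Wall-clock numbers are reported, never asserted in tests — only operator
counts, step counts and trace equivalence are test surface.  At desk scale
(d = 16, 8 neurons/dimension) optimization yields a ~4× simulation-time
speed-up in this implementation.

## Known limitations

- Only contiguous row-major views; no byte-level strides or overlapping
  view writes.
- No cross-tag fusion (e.g. folding a Copy into a DotInc) and no parallel
  scheduling of the plan; execution is single-threaded by design.
- `DotInc` merging requires equal matrix shapes (uniform BSR blocks);
  heterogeneous blocks are left unmerged rather than zero-padded.
- A view paired with a plain signal in the same slot never merges (viewed
  memory cannot be relocated).
- Set-only signals without readers are accepted as dead code and ignored by
  the optimizer.
- Rate-based neuron models are out of scope; only spiking LIF and direct
  mode are implemented.
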