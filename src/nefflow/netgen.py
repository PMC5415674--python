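"""Synthetic model generators with the structure of built NEF networks.

Built NEF models consist of many small neural populations, each contributing
a small cluster of operators (reset the input current, route the input
through views of a shared signal, encode, apply the neuron nonlinearity,
decode).  The generators here emit exactly that structure, so the optimizer
and engine can be exercised end-to-end without any external model builder:

* :func:`gen_circconv_model` — a circular-convolution (vector binding)
  network: the operation ``u = v ⊛ w`` with ``u_i = Σ_j v_j w_{(i-j) mod n}``
  realized through spectral product pairs, one small population per product.
* :func:`gen_split_ensemble_model` — a d-dimensional representation split
  across ``s`` populations of ``d/s`` dimensions each, the structure whose
  operator-count blow-up the optimizer counteracts.
* :func:`fig3_fixture` — the minimal four-operator topology on which the
  order of merges matters (view-accessing operators must merge first).
* :func:`gen_random_model` / :func:`gen_random_dag` — seeded fuzzing
  surfaces that satisfy all role invariants by construction.

Encoder/decoder weights are seeded Gaussian matrices rather than solved NEF
decoders: optimizer correctness is independent of the weight values, and
probe-trace equivalence is checked bit-for-bit against the unoptimized run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import (
    Copy,
    DependencyGraph,
    DotInc,
    ElementwiseInc,
    Model,
    Reset,
    SimNeurons,
    SignalView,
)
from .graph_core import Cluster

__all__ = [
    "CircConvSpec",
    "SplitEnsembleSpec",
    "circconv_oracle",
    "convolution_transforms",
    "gen_circconv_model",
    "gen_split_ensemble_model",
    "fig3_fixture",
    "gen_random_model",
    "gen_random_dag",
]


@dataclass
class CircConvSpec:
    """Configuration of a circular-convolution network."""

    d: int = 4               # vector dimensionality
    n_per_d: int = 8         # neurons per dimension (desk scale)
    mode: str = "lif"        # "lif" or "direct"
    seed: int = 0

    def __post_init__(self):
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.n_per_d < 1:
            raise ValueError("n_per_d must be >= 1")
        if self.mode not in ("lif", "direct"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class SplitEnsembleSpec:
    """Configuration of a split-representation network."""

    d: int = 16              # full vector dimensionality
    s: int = 4               # number of splits (must divide d)
    n: int = 8               # neurons per split group
    seed: int = 0

    def __post_init__(self):
        if self.d < 1 or self.s < 1 or self.n < 1:
            raise ValueError("d, s, n must be >= 1")
        if self.d % self.s != 0:
            raise ValueError("s must divide d")


def circconv_oracle(v, w) -> np.ndarray:
    """Brute-force circular convolution ``u_i = Σ_j v_j w_{(i-j) mod n}``.

    The double loop is deliberate: this function is the ground truth every
    other convolution path is checked against.
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if v.ndim != 1 or v.shape != w.shape:
        raise ValueError("circconv_oracle requires equal-length vectors")
    n = v.size
    u = np.zeros(n)
    for i in range(n):
        for j in range(n):
            u[i] += v[j] * w[(i - j) % n]
    return u


def convolution_transforms(d: int):
    """Real matrices (A, B, C) with ``C @ ((A v) * (B w)) = v ⊛ w``.

    Uses the half-spectrum discrete Fourier transform with the
    three-multiplication complex product: per frequency ``k`` the products
    ``(Re_k v)(Re_k w)``, ``(Im_k v)(Im_k w)`` and
    ``((Re+Im)_k v)((Re+Im)_k w)`` determine the spectrum of the
    convolution, so ``p = 3*(d//2 + 1) <= 2d + 2`` elementwise products
    suffice.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    K = d // 2 + 1
    n = np.arange(d)
    k = np.arange(K)[:, None]
    ang = 2.0 * np.pi * k * n[None, :] / d
    R = np.cos(ang)           # real part rows of the DFT
    I = -np.sin(ang)          # imaginary part rows
    A = np.vstack([R, I, R + I])
    B = A.copy()

    # inverse transform weights, folding the conjugate-symmetric half
    w_k = np.full(K, 2.0)
    w_k[0] = 1.0
    if d % 2 == 0:
        w_k[-1] = 1.0
    Cre = (w_k[None, :] / d) * np.cos(ang.T)    # d x K
    Cim = -(w_k[None, :] / d) * np.sin(ang.T)
    # U_re = m1 - m2 ; U_im = m3 - m1 - m2
    C = np.hstack([Cre - Cim, -Cre - Cim, Cim])
    return A, B, C


def gen_circconv_model(spec: CircConvSpec, v=None, w=None) -> Model:
    """Build a circular-convolution network of ``p = 3*(d//2+1)`` populations.

    Each spectral product pair gets the canonical per-population cluster:
    Reset of the routed input, an inc-Copy from a view of the concatenated
    transform signal, an encoding DotInc, a gain ElementwiseInc plus bias
    Copy, a SimNeurons population and a decoding DotInc into a view of the
    shared product vector.  The operator count therefore grows linearly with
    ``d`` (over even ``d``), which is exactly the growth the optimizer
    collapses to a constant.
    """
    d, n_per = spec.d, spec.n_per_d
    rng = np.random.default_rng(spec.seed)
    if v is None:
        v = rng.standard_normal(d)
        v /= np.linalg.norm(v)
    if w is None:
        w = rng.standard_normal(d)
        w /= np.linalg.norm(w)
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)

    A, B, C = convolution_transforms(d)
    p = A.shape[0]

    # interleave the two transforms so that each population reads one
    # contiguous (a_i, b_i) view of a single signal
    P = np.zeros((2 * p, 2 * d))
    P[0::2, :d] = A
    P[1::2, d:] = B
    Cfull = np.zeros((d, p))
    Cfull[:, :] = C

    model = Model(dt=0.001, name=f"circconv(d={d})")
    vw = model.signal("vw", initial=np.concatenate([v, w]))
    P_sig = model.signal("P", initial=P)
    tf = model.signal("tf", shape=(2 * p,))
    prod = model.signal("prod", shape=(p,))
    C_sig = model.signal("C", initial=C)
    out = model.signal("out", shape=(d,))

    model.add_op(Reset(tf))
    model.add_op(DotInc(P_sig, vw, tf))
    model.add_op(Reset(prod))
    model.add_op(Reset(out))
    model.add_op(DotInc(C_sig, prod, out))

    for i in range(p):
        in_i = model.signal(f"in_{i}", shape=(2,))
        enc_i = model.signal(f"enc_{i}", shape=(n_per,))
        J_i = model.signal(f"J_{i}", shape=(n_per,))
        spikes_i = model.signal(f"spikes_{i}", shape=(n_per,))
        volt_i = model.signal(f"volt_{i}",
                              initial=rng.uniform(0.0, 0.7, size=n_per))
        ref_i = model.signal(f"ref_{i}", shape=(n_per,))
        E_i = model.signal(f"E_{i}",
                           initial=rng.standard_normal((n_per, 2)) / np.sqrt(2))
        gain_i = model.signal(f"gain_{i}",
                              initial=rng.uniform(0.5, 1.5, size=n_per))
        bias_i = model.signal(f"bias_{i}",
                              initial=rng.uniform(0.5, 1.5, size=n_per))
        D_i = model.signal(f"D_{i}",
                           initial=rng.standard_normal((1, n_per)) / n_per)

        model.add_op(Reset(in_i))
        model.add_op(Copy(SignalView(tf, 2 * i, (2,)), in_i, inc=True))
        r_enc = model.add_op(Reset(enc_i))
        o_enc = model.add_op(DotInc(E_i, in_i, enc_i))
        r_J = model.add_op(Reset(J_i))
        o_gain = model.add_op(ElementwiseInc(gain_i, enc_i, J_i))
        o_bias = model.add_op(Copy(bias_i, J_i, inc=True))
        o_neur = model.add_op(SimNeurons(J_i, spikes_i, volt_i, ref_i))
        o_dec = model.add_op(DotInc(D_i, spikes_i, SignalView(prod, i, (1,))))
        model.clusters.append(Cluster(
            ops=[r_enc, o_enc, r_J, o_gain, o_bias, o_neur, o_dec],
            input=in_i,
            output=SignalView(prod, i, (1,)),
            fn="product",
            inc=True,
        ))

    model.add_probe(out, "out")
    model.add_probe(prod, "prod")
    model.meta = {"d": d, "v": v, "w": w, "p": p}
    model.validate()
    return model


def gen_split_ensemble_model(spec: SplitEnsembleSpec) -> Model:
    """Build a network representing a d-vector in ``s`` groups of ``d/s`` dims.

    Every group routes its slice of the shared input vector through views,
    passes it through a small LIF population and decodes into its slice of
    the shared output vector — the identity function, so direct mode maps
    input to output exactly.  The operator count grows with ``s`` at fixed
    ``d``.
    """
    d, s, n = spec.d, spec.s, spec.n
    k = d // s
    rng = np.random.default_rng(spec.seed)
    x = rng.standard_normal(d)
    x /= np.linalg.norm(x)

    model = Model(dt=0.001, name=f"split(d={d},s={s})")
    IN = model.signal("IN", initial=x)
    OUT = model.signal("OUT", shape=(d,))
    model.add_op(Reset(OUT))

    for g in range(s):
        in_g = model.signal(f"in_{g}", shape=(k,))
        J_g = model.signal(f"J_{g}", shape=(n,))
        spikes_g = model.signal(f"spikes_{g}", shape=(n,))
        volt_g = model.signal(f"volt_{g}",
                              initial=rng.uniform(0.0, 0.7, size=n))
        ref_g = model.signal(f"ref_{g}", shape=(n,))
        E_g = model.signal(f"E_{g}",
                           initial=rng.standard_normal((n, k)) / np.sqrt(k))
        bias_g = model.signal(f"bias_{g}",
                              initial=rng.uniform(0.5, 1.5, size=n))
        D_g = model.signal(f"D_{g}",
                           initial=rng.standard_normal((k, n)) / n)

        model.add_op(Reset(in_g))
        model.add_op(Copy(SignalView(IN, g * k, (k,)), in_g, inc=True))
        r_J = model.add_op(Reset(J_g))
        o_enc = model.add_op(DotInc(E_g, in_g, J_g))
        o_bias = model.add_op(Copy(bias_g, J_g, inc=True))
        o_neur = model.add_op(SimNeurons(J_g, spikes_g, volt_g, ref_g))
        o_dec = model.add_op(DotInc(D_g, spikes_g, SignalView(OUT, g * k, (k,))))
        model.clusters.append(Cluster(
            ops=[r_J, o_enc, o_bias, o_neur, o_dec],
            input=in_g,
            output=SignalView(OUT, g * k, (k,)),
            fn="identity",
            inc=True,
        ))

    model.add_probe(OUT, "OUT")
    model.meta = {"d": d, "s": s, "x": x}
    model.validate()
    return model


def fig3_fixture(seed: int = 0) -> Model:
    """Minimal topology on which merge order matters.

    Two operators (``o1``) read disjoint views of one signal ``a`` and write
    whole signals ``b1``/``b2``; two more (``o2``) read the ``b`` signals and
    write ``c1``/``c2``.  Merging the view-accessing ``o1`` pair first imposes
    the order of the ``a`` views onto the ``b`` memory, after which the
    ``o2`` pair can still merge (2 operators remain); merging the ``o2`` pair
    first in the adverse order fixes ``(b2, b1)`` and permanently blocks the
    ``o1`` merge.
    """
    rng = np.random.default_rng(seed)
    model = Model(dt=0.001, name="fig3")
    a = model.signal("a", initial=rng.standard_normal(4))
    b1 = model.signal("b1", shape=(2,))
    b2 = model.signal("b2", shape=(2,))
    c1 = model.signal("c1", shape=(2,))
    c2 = model.signal("c2", shape=(2,))
    model.add_op(Copy(SignalView(a, 0, (2,)), b1))   # o1 pair
    model.add_op(Copy(SignalView(a, 2, (2,)), b2))
    model.add_op(Copy(b1, c1))                        # o2 pair
    model.add_op(Copy(b2, c2))
    model.add_probe(c1, "c1")
    model.add_probe(c2, "c2")
    model.validate()
    return model


_RANDOM_KINDS = ("reset", "copy_set", "copy_inc", "ew_inc", "dot_inc",
                 "neurons", "split_views")


def gen_random_model(n_ops: int = 30, seed: int = 0) -> Model:
    """Random model satisfying all role invariants by construction.

    Signals are only read after all their increment operators exist, so every
    dependency edge points from an earlier-created operator to a later one
    and the graph is acyclic by construction.  Incremented signals always
    have a Reset setter.  Probes cover every written base signal, making
    optimized-vs-unoptimized trace comparison exhaustive.
    """
    if n_ops < 0:
        raise ValueError("n_ops must be >= 0")
    rng = np.random.default_rng(seed)
    model = Model(dt=0.001, name=f"random({n_ops},seed={seed})")

    counter = [0]

    def new_sig(length, initial=None):
        counter[0] += 1
        name = f"s{counter[0]}"
        if initial is None:
            return model.signal(name, shape=(length,))
        return model.signal(name, initial=initial)

    readable: list = []   # value defined before any later reader
    inc_open: list = []   # has a Reset setter; still accepts increments
    written: list = []    # probed at the end

    for _ in range(3):
        readable.append(new_sig(int(rng.integers(1, 5)),
                                initial=rng.standard_normal(int(rng.integers(1, 5)))))

    def pick_read(length=None):
        pool = [s for s in readable if length is None or s.size == length]
        if not pool:
            L = length if length is not None else int(rng.integers(1, 5))
            s = new_sig(L, initial=rng.standard_normal(L))
            pool = [s]
            readable.append(s)
        s = pool[int(rng.integers(len(pool)))]
        if s in inc_open:  # reading closes the signal for future increments
            inc_open.remove(s)
        return s

    def open_target(length=None):
        pool = [s for s in inc_open if length is None or s.size == length]
        if pool:
            return pool[int(rng.integers(len(pool)))]
        L = length if length is not None else int(rng.integers(1, 5))
        s = new_sig(L)
        model.add_op(Reset(s))
        inc_open.append(s)
        readable.append(s)
        written.append(s)
        return s

    while len(model.operators) < n_ops:
        kind = _RANDOM_KINDS[int(rng.integers(len(_RANDOM_KINDS)))]
        if kind == "reset":
            s = new_sig(int(rng.integers(1, 5)))
            model.add_op(Reset(s))
            inc_open.append(s)
            readable.append(s)
            written.append(s)
        elif kind == "copy_set":
            src = pick_read()
            dst = new_sig(src.size)
            model.add_op(Copy(src, dst))
            inc_open.append(dst)
            readable.append(dst)
            written.append(dst)
        elif kind == "copy_inc":
            dst = open_target()
            src = pick_read(dst.size)
            model.add_op(Copy(src, dst, inc=True))
        elif kind == "ew_inc":
            dst = open_target()
            A = pick_read(dst.size)
            X = pick_read(dst.size)
            model.add_op(ElementwiseInc(A, X, dst))
        elif kind == "dot_inc":
            dst = open_target()
            src = pick_read()
            W = new_sig(0, initial=rng.standard_normal((dst.size, src.size)))
            model.add_op(DotInc(W, src, dst))
        elif kind == "neurons":
            J = pick_read()
            out = new_sig(J.size)
            volt = new_sig(0, initial=rng.uniform(0, 0.7, size=J.size))
            ref = new_sig(J.size)
            model.add_op(SimNeurons(J, out, volt, ref))
            readable.append(out)
            written.append(out)
        elif kind == "split_views":
            L = int(rng.integers(1, 4))
            base = new_sig(2 * L)
            model.add_op(Reset(base))
            s1 = pick_read(L)
            s2 = pick_read(L)
            model.add_op(Copy(s1, SignalView(base, 0, (L,)), inc=True))
            model.add_op(Copy(s2, SignalView(base, L, (L,)), inc=True))
            readable.append(base)
            written.append(base)

    for s in written:
        model.add_probe(s, s.name)
    model.clusters = []
    model.validate()
    return model


def gen_random_dag(n: int, p: float, seed: int = 0) -> DependencyGraph:
    """Random DAG over integer vertices via ordered-pair coin flips.

    Edges only point from lower to higher vertex index, guaranteeing
    acyclicity; edge (i, j) exists with probability ``p``.
    """
    if n < 0 or not (0.0 <= p <= 1.0):
        raise ValueError("need n >= 0 and 0 <= p <= 1")
    rng = np.random.default_rng(seed)
    g = DependencyGraph(vertices=range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g
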