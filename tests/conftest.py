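import numpy as np
import pytest

from nefflow.graph_core import (
    Copy,
    DotInc,
    ElementwiseInc,
    Model,
    Reset,
    SimNeurons,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def two_population_model(seed=0):
    """Two unrelated input-current clusters (copy, encode, neurons), the
    canonical mergeable pattern."""
    rng = np.random.default_rng(seed)
    m = Model(dt=0.001, name="two_pop")
    for i in range(2):
        src = m.signal(f"src_{i}", initial=rng.standard_normal(2))
        in_i = m.signal(f"in_{i}", shape=(2,))
        J = m.signal(f"J_{i}", shape=(3,))
        E = m.signal(f"E_{i}", initial=rng.standard_normal((3, 2)))
        out = m.signal(f"out_{i}", shape=(3,))
        volt = m.signal(f"volt_{i}", shape=(3,))
        ref = m.signal(f"ref_{i}", shape=(3,))
        gain = m.signal(f"gain_{i}", initial=rng.uniform(0.5, 1.5, 3))
        one = m.signal(f"one_{i}", initial=np.ones(3))
        m.add_op(Reset(in_i))
        m.add_op(Copy(src, in_i, inc=True))
        m.add_op(Reset(J))
        m.add_op(DotInc(E, in_i, J))
        m.add_op(ElementwiseInc(gain, one, J))
        m.add_op(SimNeurons(J, out, volt, ref))
        m.add_probe(out, f"out_{i}")
        m.add_probe(J, f"J_{i}")
    m.validate()
    return m


@pytest.fixture
def two_pop_model():
    return two_population_model()
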