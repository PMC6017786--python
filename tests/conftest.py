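import numpy as np
import pytest

from ssetop.structure_io import (
    ChainModel,
    ChainResidue,
    SequenceSegment,
    Stick,
)


@pytest.fixture
def straight_chain():
    """12 residues along z at the canonical 3.8 Å CA step."""
    residues = [
        ChainResidue(
            index=i,
            aa="A",
            ca=np.array([0.0, 0.0, 3.8 * (i - 1)]),
            n=np.array([0.0, -0.5, 3.8 * (i - 1) - 0.4]),
            c=np.array([0.0, 0.5, 3.8 * (i - 1) + 0.4]),
        )
        for i in range(1, 13)
    ]
    return ChainModel(chain_id="A", residues=residues)


@pytest.fixture
def two_segments():
    """Two helix segments separated by a 3-residue loop."""
    return (
        SequenceSegment(1, "H", 1, 10),
        SequenceSegment(2, "H", 14, 23),
    )


def make_random_problem(rng, max_m=4, max_n=5):
    """Random typed segments and sticks with a feasibility-prone layout.

    Used by the solver oracle tests; stick count N <= max_n overall.
    """
    m_h = int(rng.integers(1, max_m))
    n_h = int(rng.integers(1, m_h + 1))
    m_b = int(rng.integers(0, 3))
    n_b = int(rng.integers(0, m_b + 1)) if m_b else 0
    if n_h + n_b > max_n:
        n_b = max(0, max_n - n_h)
        m_b = max(m_b, n_b)
    segments = []
    types = ["H"] * m_h + ["E"] * m_b
    rng.shuffle(types)
    pos = 1
    for k, t in enumerate(types):
        length = int(rng.integers(6, 10))
        segments.append(SequenceSegment(k + 1, t, pos, pos + length - 1))
        pos += length + int(rng.integers(2, 8))
    sticks = []
    j = 1
    for t in ["H"] * n_h + ["E"] * n_b:
        p0 = rng.uniform(0.0, 30.0, 3)
        p1 = p0 + rng.uniform(3.0, 12.0, 3)
        sticks.append(Stick(j, t, p0, p1))
        j += 1
    return segments, sticks
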