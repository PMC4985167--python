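import numpy as np
import pytest

from seqfam.descriptors import PropertyGrouping, load_groupings, load_scales
from seqfam.sequence_io import CANONICAL_AA, ProteinSequence

# 30-residue two-letter example used across descriptor tests
EXAMPLE_RESIDUES = "AEAAAEAEEAAAAAEAEEEAAEEAEEEAAE"


@pytest.fixture(scope="session")
def groupings():
    return load_groupings()


@pytest.fixture(scope="session")
def scales():
    return load_scales()


@pytest.fixture(scope="session")
def example_seq():
    return ProteinSequence("example", EXAMPLE_RESIDUES)


@pytest.fixture(scope="session")
def ae_grouping(groupings):
    """A grouping that places A and E in different classes."""
    g = groupings["hydrophobicity"]
    assert g.class_of["A"] != g.class_of["E"]
    return g


def random_sequence(rng: np.random.Generator, length: int, seq_id: str = "r") -> ProteinSequence:
    residues = "".join(CANONICAL_AA[i] for i in rng.integers(0, 20, size=length))
    return ProteinSequence(seq_id, residues)


def random_grouping(rng: np.random.Generator, name: str = "rand") -> PropertyGrouping:
    """A random 3-class partition with every class non-empty."""
    while True:
        classes = rng.integers(1, 4, size=20)
        if set(classes.tolist()) == {1, 2, 3}:
            break
    return PropertyGrouping(name, dict(zip(CANONICAL_AA, (int(c) for c in classes))))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
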