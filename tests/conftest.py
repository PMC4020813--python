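import numpy as np
import pytest

from seqscm.seqio import LabeledDataset, ProteinSequence
from seqscm.alphabet import AMINO_ACIDS


def make_seq(residues: str, id: str = "s") -> ProteinSequence:
    return ProteinSequence(id=id, residues=residues)


def random_seq(rng: np.random.Generator, length: int, id: str = "s") -> ProteinSequence:
    letters = rng.choice(list(AMINO_ACIDS), size=length)
    return ProteinSequence(id=id, residues="".join(letters))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """20+20 random sequences of length 60-100 (no planted signal)."""
    pos = [random_seq(rng, int(rng.integers(60, 101)), f"p{i}") for i in range(20)]
    neg = [random_seq(rng, int(rng.integers(60, 101)), f"n{i}") for i in range(20)]
    return LabeledDataset(positives=pos, negatives=neg, name="random40")
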