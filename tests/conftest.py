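import numpy as np
import pytest

from promoterlstm.sequence_io import DnaSequence

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int, id: str = "seq") -> DnaSequence:
    return DnaSequence(id=id, residues="".join(rng.choice(list(BASES), size=length)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def promoter_300(rng) -> DnaSequence:
    return random_dna(rng, 300, id="pro_fixture")
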