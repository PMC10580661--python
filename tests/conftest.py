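import numpy as np
import pytest

from kdeep.seqio import NucleotideStrand

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, length: int, alphabet: str = BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def random_strand(rng: np.random.Generator, length: int, sid: str = "s") -> NucleotideStrand:
    return NucleotideStrand(id=sid, sequence=random_sequence(rng, length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
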