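import numpy as np
import pytest

from cpgprom import height_fixture
from cpgprom.core import SequenceRecord


@pytest.fixture(scope="session")
def fixture_genes():
    return height_fixture.load_fixture()


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """IID nucleotide sequence with the given expected G+C fraction."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


@pytest.fixture
def random_record():
    def make(seed: int, length: int = 1000, gc: float = 0.5) -> SequenceRecord:
        rng = np.random.default_rng(seed)
        return SequenceRecord(id=f"rand{seed}", seq=random_sequence(rng, length, gc))

    return make
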