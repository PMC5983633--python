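import numpy as np
import pytest

from mirstalk.seqio import SequenceRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_genome(rng) -> list[SequenceRecord]:
    return [
        SequenceRecord("chr1", random_seq(rng, 2000)),
        SequenceRecord("chr2", random_seq(rng, 1500)),
    ]
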