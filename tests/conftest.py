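import numpy as np
import pytest

from dbcbin import SequenceRecord, make_models


def random_acgt(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_records():
    return [
        SequenceRecord("a", "ACGTACGTACGT", "first contig"),
        SequenceRecord("b", "GGCCGGAATTCC"),
        SequenceRecord("c", "ACGTNNACGTTT"),
    ]


@pytest.fixture(scope="session")
def two_models():
    """Two well-separated genome models shared across classifier tests."""
    return make_models(2, separation=0.8, seed=4242)
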