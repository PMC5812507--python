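import numpy as np
import pytest

from nanocurate.io_formats import Genome, SequenceRecord

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_genome(rng):
    """Two repeat-free replicons totalling 30 kb."""
    return Genome([
        (SequenceRecord("chrI", random_seq(rng, 10_000)), False),
        (SequenceRecord("chrII", random_seq(rng, 20_000)), False),
    ], name="toy")
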