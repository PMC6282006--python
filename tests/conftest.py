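import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from tandemreads.records import SequenceRecord
from tandemreads.simulate import _random_bases


@pytest.fixture
def rng():
    return np.random.default_rng(20181205)


@pytest.fixture
def random_reference(rng) -> SequenceRecord:
    """A 2 kb random reference with no planted structure."""
    return SequenceRecord(id="ref", sequence=_random_bases(rng, 2000))


def random_read(rng, length: int, alphabet: str = "ACGT") -> SequenceRecord:
    bases = np.array(list(alphabet))
    seq = "".join(bases[rng.integers(0, len(bases), length)])
    # SequenceRecord forbids empty; callers pass length >= 1
    return SequenceRecord(id="r", sequence=seq)
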