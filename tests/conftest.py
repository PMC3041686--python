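import numpy as np
import pytest

from sporesort import AlignedSequenceSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_alignment():
    """Three distinct 12-column sequences plus one duplicate."""
    return AlignedSequenceSet(
        ids=["cl1", "cl2", "cl3", "cl4"],
        sequences=[
            "ACGTACGTACGT",
            "ACGTACGTACGT",
            "ACGTACGTACGA",
            "ACGTTCGTACGA",
        ],
    )


def random_sequences(rng, n, length):
    bases = np.array(list("ACGT"))
    return ["".join(bases[rng.integers(0, 4, size=length)]) for _ in range(n)]
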