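import numpy as np
import pytest

from top1tam.synthetic_data import generate_genome


@pytest.fixture(scope="session")
def seed13_genome():
    """2 kb genome with a mixed plan of planted repeats (session-wide)."""
    return generate_genome(
        2000,
        seed=13,
        repeat_plan=[
            ("STR", 1, 5, 2),
            ("STR", 2, 3, 3),
            ("STR", 2, 4, 1, "CT"),
            ("STR", 3, 3, 2),
            ("MH", 2, 0, 3),
            ("MH", 3, 0, 2),
        ],
    )


@pytest.fixture(scope="session")
def seed13_sequence(seed13_genome):
    return seed13_genome.sequences["chr1"]


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
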