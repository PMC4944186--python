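import random

import pytest

from lr16s.synth import generate_reference_db


@pytest.fixture(scope="session")
def small_db():
    """4 genera x 3 species reference DB at the generator defaults."""
    return generate_reference_db(4, 3, seed=11)


@pytest.fixture(scope="session")
def tiny_db():
    """2 genera x 2 species DB for cheap classification tests."""
    return generate_reference_db(2, 2, seed=5)


@pytest.fixture()
def rnd():
    return random.Random(12345)


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))
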