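import numpy as np
import pytest

from nucleocgr.physchem_features import load_index_table
from nucleocgr.synthetic_data import GeneratorSpec, generate_dataset

BASES = "ACGT"


def random_seq(rng: np.random.Generator, L: int) -> str:
    return "".join(rng.choice(list(BASES), L))


@pytest.fixture(scope="session")
def dinuc_table():
    return load_index_table("helical-steps", 2)


@pytest.fixture(scope="session")
def trinuc_table():
    return load_index_table("bendability", 3)


@pytest.fixture(scope="session")
def small_dataset():
    """120-sequence separable markov dataset shared by pipeline-level tests."""
    return generate_dataset(
        GeneratorSpec(n_pos=60, n_neg=60, L=147, mode="markov", effect=0.8, seed=11)
    )
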