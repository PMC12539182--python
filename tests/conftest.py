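import random

import pytest

from obpcur.synthetic import DEFAULT_GENERATOR, GeneratorConfig, generate_dataset

AAS = "ARNDCQEGHILKMFPSTWYV"


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study conditions at seed 42 (shared, read-only)."""
    return generate_dataset(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down generator config for fast end-to-end runs."""
    return GeneratorConfig(seed=7, n_refs=20, n_genes=8, decoy_count=5,
                           expansion=False)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


def random_protein(rng: random.Random, n: int, alphabet: str = AAS) -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def sequence_with_cysteines(positions, length, fill="A"):
    """Protein of ``length`` with C exactly at the given 1-based positions."""
    seq = [fill] * length
    for p in positions:
        seq[p - 1] = "C"
    return "".join(seq)
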