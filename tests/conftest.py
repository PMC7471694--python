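import numpy as np
import pytest

from padbench.codec import build_alphabet, default_alphabet
from padbench import data as ds
from padbench.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def alphabet():
    return default_alphabet()


@pytest.fixture(scope="session")
def tiny_alphabet():
    return build_alphabet(["A", "B", "C"])


@pytest.fixture(scope="session")
def small_records():
    """200 synthetic annotated sequences, default study conditions."""
    return simulate_dataset(SimulationConfig(n_sequences=200, seed=42))


@pytest.fixture(scope="session")
def small_samples(small_records):
    return ds.expand_multi_ec(ds.filter_by_length(small_records))


@pytest.fixture
def rng():
    return np.random.default_rng(7)
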