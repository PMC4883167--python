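import numpy as np
import pytest
from hypothesis import settings

from eegtexture import SynthConfig, generate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_dataset():
    """20 synthetic signals (10 per class), shared across tests."""
    return generate_dataset(SynthConfig(n_per_class=10, seed=7))


@pytest.fixture(scope="session")
def one_normal(small_dataset):
    return small_dataset[0]


@pytest.fixture(scope="session")
def one_seizure(small_dataset):
    return small_dataset[-1]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
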