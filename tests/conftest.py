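import numpy as np
import pytest

from mcqsar.data import random_split, synthesize_dataset
from mcqsar.optimizer import OptimizationConfig


@pytest.fixture(scope="session")
def small_dataset():
    """60 synthetic molecules with a planted 8-attribute signal."""
    records, truth = synthesize_dataset(
        n_molecules=60, n_signal_attributes=8, noise_sd=0.08, seed=11
    )
    return records, truth


@pytest.fixture(scope="session")
def small_split(small_dataset):
    records, _ = small_dataset
    return random_split(records, seed=11)


@pytest.fixture(scope="session")
def quick_config():
    """A config sized for unit tests: fewer epochs and restarts."""
    return OptimizationConfig(seed=11, epochs=4, restarts=2, pair_probe_factor=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
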