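import numpy as np
import pytest

from nirselect import SimulationConfig, generate, to_absorbance


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully-featured simulation: 40 fruit on a 256-point grid."""
    return SimulationConfig(n_samples=40, n_wavelengths=256, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def small_absorbance(small_dataset):
    sset, ref, gt = small_dataset
    return to_absorbance(sset), ref, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
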