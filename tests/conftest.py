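import numpy as np
import pytest

from roidistill import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """80-patient synthetic dataset shared by read-only tests."""
    samples, manifest = generate_dataset(GeneratorConfig(n_patients=80, seed=11))
    return samples, manifest


@pytest.fixture(scope="session")
def medium_samples():
    """200-patient dataset for frequency/split statistics."""
    samples, _ = generate_dataset(GeneratorConfig(n_patients=200, seed=7))
    return samples


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
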