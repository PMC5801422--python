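import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from rhythmboot import (  # noqa: E402
    BootstrapConfig,
    DetectorMethod,
    SyntheticConfig,
    fit_all_genes,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_config():
    """A fast 30-gene synthetic design used across the suite."""
    return SyntheticConfig(G=30, P=4, T=24, fraction_rhythmic=0.4, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    dataset, truth = generate_dataset(small_config)
    return dataset, truth


@pytest.fixture(scope="session")
def small_fits(small_dataset):
    dataset, _ = small_dataset
    return fit_all_genes(dataset)


@pytest.fixture
def cosinor():
    return DetectorMethod("cosinor_f", period=12)


@pytest.fixture
def boot_config():
    return BootstrapConfig(B=5, seed=23)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
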