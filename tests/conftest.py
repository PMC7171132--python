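import numpy as np
import pytest
from hypothesis import settings

from reservecalc import synthetic as sy

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free study-condition configuration (small gene count for speed)."""
    return sy.SynthConfig(n_genes=800, noise_cv=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return sy.generate_chemostat_omics(clean_config)


@pytest.fixture(scope="session")
def noisy_dataset():
    return sy.generate_chemostat_omics(sy.SynthConfig(n_genes=2000, noise_cv=0.2, seed=7))


@pytest.fixture(scope="session")
def linear_model():
    return sy.generate_toy_model("linear")


@pytest.fixture(scope="session")
def branched_model():
    return sy.generate_toy_model("branched-fermentation")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
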