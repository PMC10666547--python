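import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from toxprio.synthetic_data import GeneratorConfig, generate_training, make_fixture


@pytest.fixture(scope="session")
def curation6():
    return make_fixture("curation6")


@pytest.fixture(scope="session")
def blobs4():
    return make_fixture("blobs4")


@pytest.fixture(scope="session")
def ad5():
    return make_fixture("ad5")


@pytest.fixture(scope="session")
def small_training():
    """A small discontinuous-response synthetic training set."""
    cfg = GeneratorConfig(n_chemicals=150, n_descriptors=30, n_latent=16,
                          response="discontinuous", seed=5)
    return generate_training(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
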