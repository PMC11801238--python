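import numpy as np
import pytest

from vdnmr.simulate import GeneratorConfig, generate_training_set


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def sample_set(gen_config):
    """One deterministic default-condition training set, shared per session."""
    return generate_training_set(gen_config, 42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
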