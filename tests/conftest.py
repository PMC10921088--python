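import numpy as np
import pytest

from watunet.phantom import PhantomConfig, generate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return PhantomConfig(n_samples=6, image_size=(64, 64), seed=3)


@pytest.fixture
def benign_sample(small_config):
    return generate_sample(small_config, "benign", np.random.default_rng(7))


@pytest.fixture
def malignant_sample(small_config):
    return generate_sample(small_config, "malignant", np.random.default_rng(8))
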