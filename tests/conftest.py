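import numpy as np
import pytest

from ctcforge.fixtures import FixtureConfig, make_detection_dataset


@pytest.fixture(scope="session")
def small_config():
    return FixtureConfig(n_images=6, image_size=96, n_classes=2,
                         cell_radius=(6.0, 12.0), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return make_detection_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
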