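import numpy as np
import pytest

import gradefusion as gf


@pytest.fixture(scope="session")
def default_config():
    return gf.SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def dataset(default_config):
    """The default synthetic world: 15 samples per grade, both modalities."""
    return gf.simulate_dataset(default_config)


@pytest.fixture(scope="session")
def enose_table(dataset):
    recordings, _, _ = dataset
    return gf.enose_feature_table(recordings)


@pytest.fixture(scope="session")
def image_table(dataset):
    _, images, _ = dataset
    return gf.image_feature_table(images)


@pytest.fixture(scope="session")
def fused_table(image_table, enose_table):
    return gf.fuse_features(image_table, enose_table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
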