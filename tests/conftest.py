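import numpy as np
import pytest

from eegsense.features import build_feature_table
from eegsense.synth import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Small strongly-separated two-group dataset shared across tests."""
    cfg = SynthConfig(
        n_per_group=6, n_channels=4, n_epochs_per_subject=3,
        effect_size=3.0, seed=11,
    )
    return cfg, generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    _cfg, epochs = small_dataset
    return build_feature_table(epochs)
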