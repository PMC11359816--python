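import numpy as np
import pytest

from raftseg import NetworkConfig, build_model, generate_training_tiles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest legal network: 32-px tiles, 1/8 widths."""
    return NetworkConfig(tile_size=32, width_multiplier=0.125)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return build_model(tiny_config, seed=7)


@pytest.fixture(scope="session")
def small_tiles():
    """Eight 32-px synthetic raft tiles for fast training tests."""
    return generate_training_tiles(8, size=32, seed=42)
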