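import numpy as np
import pytest

from classm.stainsep import RGBTile
from classm.synthesis import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def white_tile():
    return RGBTile(np.full((8, 8, 3), 255, dtype=np.int64), 255.0, "s0")


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small in-memory synthetic dataset shared across tests."""
    return generate_dataset(
        n_slides=5,
        n_labeled_per_class=6,
        n_unlabeled=24,
        n_val_per_class=4,
        n_test_per_class=4,
        tile_size=64,
        seed=7,
    )
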