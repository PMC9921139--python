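import numpy as np
import pytest

from macs.asdb import ASDB, ModelConfig
from macs.phantom import PhantomConfig, generate_dataset


@pytest.fixture(scope="session")
def small_phantoms():
    """16 labeled 64x64 source-domain phantoms."""
    cfg = PhantomConfig(image_size=64, n_images=16, epi_margin_range=(2, 5), seed=7)
    return generate_dataset(cfg)


@pytest.fixture()
def tiny_model():
    return ASDB(ModelConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_mask(rng: np.random.Generator, size: int = 32) -> np.ndarray:
    """Random connected-ish blob mask (possibly empty)."""
    kind = rng.integers(0, 3)
    if kind == 0:
        return np.zeros((size, size), dtype=bool)
    rows, cols = np.mgrid[0:size, 0:size]
    cy, cx = rng.uniform(4, size - 4, 2)
    a, b = rng.uniform(2, size / 3, 2)
    mask = ((rows - cy) / a) ** 2 + ((cols - cx) / b) ** 2 <= 1.0
    if kind == 2:  # speckle the edge to exercise odd contours
        noise = rng.random((size, size)) < 0.05
        mask = mask ^ (mask & noise)
    return mask
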