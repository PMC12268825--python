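import numpy as np
import pytest

from fibroscar.preprocess import MaskSource, ROIMask
from fibroscar.radiomics.discretize import DiscretizedImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_discretized(rng, shape=(8, 8), n_levels=4, mask_fraction=1.0):
    """A random small discretized image with an optional partial mask."""
    mask = np.ones(shape, dtype=bool)
    if mask_fraction < 1.0:
        mask = rng.random(shape) < mask_fraction
        if not mask.any():
            mask[shape[0] // 2, shape[1] // 2] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, int(mask.sum()))
    d = DiscretizedImage(levels=levels, n_levels=n_levels,
                         mask=ROIMask(mask=mask, source=MaskSource.MANUAL))
    return d


@pytest.fixture
def full_mask():
    def make(shape):
        return ROIMask(mask=np.ones(shape, dtype=bool), source=MaskSource.MANUAL)
    return make
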