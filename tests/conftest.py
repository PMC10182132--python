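import numpy as np
import pytest

from dtdsmil.features import FeatureBag


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_bag(rng, n=6, d=8, grid_shape=(3, 3), label=None, slide_id="t"):
    cells = np.stack(np.meshgrid(np.arange(grid_shape[1]),
                                 np.arange(grid_shape[0])), axis=-1).reshape(-1, 2)
    coords = cells[rng.choice(len(cells), size=n, replace=False)]
    tokens = rng.normal(size=(n, d))
    return FeatureBag(tokens=tokens, coords=coords, grid_shape=grid_shape,
                      slide_id=slide_id, label=label)


@pytest.fixture
def small_bag(rng):
    return make_bag(rng)
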