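import numpy as np
import pytest
from hypothesis import settings

from azcalcium import IntensityMap

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_map(values, background=None) -> IntensityMap:
    """IntensityMap from a 2-D array; full mask unless background given."""
    values = np.asarray(values, dtype=float)
    if background is None:
        background = np.zeros(values.shape, dtype=bool)
    grid = values.copy()
    grid[background] = np.nan
    return IntensityMap(grid=grid, background_mask=np.asarray(background, bool))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_masked_maps(rng):
    """A battery of random maps with assorted mask geometries."""
    maps = []
    for k in range(8):
        h, w = rng.integers(3, 12, size=2)
        values = rng.normal(size=(h, w))
        background = rng.random((h, w)) < (0.0 if k < 2 else 0.3)
        if background.all():
            background[h // 2, w // 2] = False
        maps.append(make_map(values, background))
    return maps
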