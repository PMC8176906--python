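"""Shared fixtures: small DEMs and the standard synthetic island."""

import numpy as np
import pytest

from lcvmap.grids import Raster
from lcvmap.synth import IslandParams, gen_dem


@pytest.fixture(scope="session")
def island_dem() -> Raster:
    """The 64x64 seed-7 synthetic island used by the end-to-end checks."""
    return gen_dem(IslandParams(seed=7))


@pytest.fixture(scope="session")
def cone_dem() -> Raster:
    """A smooth oreum-free, channel-free cone (noise 0)."""
    return gen_dem(IslandParams(seed=7, n_oreums=0, channel_count=0, noise_sd=0.0))


@pytest.fixture
def tilted_plane() -> Raster:
    """z = x with 1 m cells: a 45-degree plane dipping west-to-east... rising east."""
    x = np.arange(8, dtype=float)
    return Raster(np.tile(x, (8, 1)), cell_size=1.0)


def make_raster(values, cell_size=30.0, **kw) -> Raster:
    return Raster(np.asarray(values, dtype=float), cell_size=cell_size, **kw)
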