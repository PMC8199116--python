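import numpy as np
import pytest

from lurex.pipeline import RunConfig, run_stages
from lurex.raster import GridRaster


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default-city run shared by the slower integration tests."""
    return run_stages(RunConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_raster(rng):
    """5x5 raster with unit cells, values 0..24."""
    return GridRaster(np.arange(25, dtype=float).reshape(5, 5),
                      cell_size_m=1.0, units="unitless", name="toy")


def constant_raster(value, shape=(6, 6), cell=90.0, **kw):
    return GridRaster(np.full(shape, float(value)), cell_size_m=cell, **kw)


@pytest.fixture()
def make_constant_raster():
    return constant_raster
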