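import numpy as np
import pytest

from woodchange.grids import FractionalCoverMap, Grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid10():
    return Grid(0.0, 0.0, 1.0, 10, 10)


@pytest.fixture
def fractional_map_factory(rng):
    """Factory for random fractional maps on a unit-cell grid."""

    def make(n_rows=10, n_cols=10, cell_size=1.0, epoch=2020, nodata_frac=0.0, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        grid = Grid(0.0, 0.0, cell_size, n_rows, n_cols)
        values = r.random((n_rows, n_cols))
        mask = r.random((n_rows, n_cols)) < nodata_frac
        values[mask] = np.nan
        return FractionalCoverMap(grid, values, mask, epoch)

    return make
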