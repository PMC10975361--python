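import numpy as np
import pytest

from stinterp.core import StationGrid, STSeries


@pytest.fixture(scope="session")
def grid7x10() -> StationGrid:
    return StationGrid.regular(7, 10)


@pytest.fixture(scope="session")
def grid5x5() -> StationGrid:
    return StationGrid.regular(5, 5, lon0=52.0, lat0=26.0, spacing_lon=0.5, spacing_lat=0.5)


@pytest.fixture(scope="session")
def random_series_5x5(grid5x5) -> STSeries:
    """Strictly positive 25-station × 6-month random field."""
    rng = np.random.default_rng(42)
    values = 50.0 + 10.0 * rng.standard_normal((25, 6))
    return STSeries(grid5x5, values)


@pytest.fixture(scope="session")
def planar_series_7x10(grid7x10) -> STSeries:
    """Noise-free planar field, constant in time."""
    g = grid7x10
    plane = 2.0 * (g.lon - g.lon.mean()) + 3.0 * (g.lat - g.lat.mean()) + 10.0
    return STSeries(g, np.repeat(plane[:, None], 3, axis=1))


def per_station_mae(folds):
    return np.array([np.mean(np.abs(f.observed - f.predicted)) for f in folds])


def edge_masks(n_rows=7, n_cols=10):
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    edge = (rows == 0) | (rows == n_rows - 1) | (cols == 0) | (cols == n_cols - 1)
    corner = ((rows == 0) | (rows == n_rows - 1)) & ((cols == 0) | (cols == n_cols - 1))
    return edge, corner
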