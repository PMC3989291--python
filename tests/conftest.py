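import warnings

import numpy as np
import pytest

from lagoonconnect.domain import (
    LagoonGrid, build_idealized_lagoon, partition_sectors, stretched_sigma_edges,
)
from lagoonconnect.circulation import CirculationModel, CirculationParams


@pytest.fixture(scope="session")
def lagoon():
    """Standard desk-scale lagoon: ~142 km^2, 41 m mean depth, 8 layers."""
    return build_idealized_lagoon(area_km2=142.0, mean_depth_m=41.0,
                                  max_depth_m=70.0, n_sigma=8, dx_m=500.0)


@pytest.fixture(scope="session")
def sectors(lagoon):
    return partition_sectors(lagoon, k=12, seed=0)


@pytest.fixture(scope="session")
def circulation(lagoon):
    return CirculationModel(lagoon, CirculationParams())


@pytest.fixture(scope="session")
def tiny_grid():
    """5x5 wet patch, 3 sigma layers, one pass + one hoa cell."""
    depth = np.zeros((7, 7))
    depth[1:6, 1:6] = 20.0
    depth[3, 1] = 11.0   # pass on the western rim
    depth[1, 3] = 0.3    # hoa on the southern rim
    return LagoonGrid(nx=7, ny=7, dx=200.0, dy=200.0, depth=depth, n_sigma=3,
                      sigma_edges=stretched_sigma_edges(3, 0.5),
                      boundary_cells={(3, 1): "pass", (1, 3): "hoa"})


@pytest.fixture(scope="session")
def tiny_sectors(tiny_grid):
    return partition_sectors(tiny_grid, k=2, seed=1)


@pytest.fixture(autouse=True)
def _quiet_band_clipping():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="release band .* clipped")
        yield
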