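import numpy as np
import pandas as pd
import pytest

from urbannpp import (
    FishnetGrid,
    SyntheticCityConfig,
    add_impacts,
    aggregate_to_fishnet,
    estimate_npp_fv,
    generate_city,
)


def make_lattice_grid(nrows: int, ncols: int, cell_size: float = 1.0) -> FishnetGrid:
    """A fully valid rectangular fishnet with unit-less coordinates."""
    rows, cols = np.divmod(np.arange(nrows * ncols), ncols)
    table = pd.DataFrame(
        {
            "id": np.arange(nrows * ncols),
            "row": rows,
            "col": cols,
            "u": (cols + 0.5) * cell_size,
            "v": (nrows - rows - 0.5) * cell_size,
        }
    )
    return FishnetGrid(table=table, cell_size=cell_size, crs="EPSG:32648",
                       nrows=nrows, ncols=ncols, origin=(0.0, nrows * cell_size))


def brute_force_global_moran(values, W_dense) -> float:
    """Independent O(n^2) double-loop evaluation of global Moran's I."""
    y = np.asarray(values, float)
    n = y.size
    ybar = y.mean()
    s2 = ((y - ybar) ** 2).sum() / n
    num = 0.0
    w0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W_dense[i, j] * (y[i] - ybar) * (y[j] - ybar)
            w0 += W_dense[i, j]
    return num / (s2 * w0)


def brute_force_local_moran(values, W_dense) -> np.ndarray:
    """Independent double-loop evaluation of the per-cell local Moran."""
    y = np.asarray(values, float)
    n = y.size
    ybar = y.mean()
    s2 = ((y - ybar) ** 2).sum() / n
    out = np.empty(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            acc += W_dense[i, j] * (y[j] - ybar)
        out[i] = (y[i] - ybar) / s2 * acc
    return out


def brute_force_wls(Xd, y, w) -> np.ndarray:
    """Independent weighted-normal-equations solve via pseudoinverse."""
    sw = np.sqrt(np.asarray(w, float))
    return np.linalg.pinv(sw[:, None] * Xd) @ (sw * np.asarray(y, float))


@pytest.fixture(scope="session")
def default_city():
    """The default synthetic city (60x60 cells, fixed seed)."""
    return generate_city(SyntheticCityConfig(seed=1))


@pytest.fixture(scope="session")
def default_city_grid(default_city):
    """Fishnet table of the default city with impacts from true NPP_fv."""
    cfg = default_city.config
    grid = aggregate_to_fishnet(default_city.all_layers(), cfg.cell_size)
    npp_fv = estimate_npp_fv(grid, mode="supplied", supplied_column="npp_fv_true")
    return add_impacts(grid, npp_fv)


@pytest.fixture
def small_city():
    """A fast 16x16 city for structural tests."""
    return generate_city(SyntheticCityConfig(grid_n=16, seed=7))
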