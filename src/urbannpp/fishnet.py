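"""Fishnet aggregation: block means of fine rasters on a coarse square grid.

Every analysis in the package operates on one joint cell table: regular
square cells (the "fishnet", e.g. 500 m) with center coordinates (u, v) and
one aggregated value per variable per cell. A cell enters the table only if
it is valid in every variable, so Moran, OLS and GWR all share one support.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RasterError
from .raster import RasterLayer

logger = logging.getLogger(__name__)


@dataclass
class FishnetGrid:
    """Joint per-cell table on a regular square lattice.

    ``table`` has columns id, row, col, u, v plus one column per variable;
    (u, v) are projected cell-center coordinates in meters.
    """

    table: pd.DataFrame
    cell_size: float
    crs: str
    nrows: int
    ncols: int
    origin: tuple[float, float]  # upper-left corner of the lattice

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def coords(self) -> np.ndarray:
        return self.table[["u", "v"]].to_numpy(dtype=float)

    def variables(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("id", "row", "col", "u", "v")]


def aggregate_to_fishnet(
    layers: dict[str, RasterLayer],
    cell_size: float,
    min_valid_fraction: float = 0.5,
) -> FishnetGrid:
    """Aggregate co-registered rasters to a fishnet of ``cell_size`` meters.

    Each source pixel is assigned to the fishnet cell containing its center;
    a cell's value is the mean of its valid pixels. Cells whose valid-pixel
    fraction falls below ``min_valid_fraction`` in a variable are masked
    there, and cells masked in any variable are dropped from the joint table.
    The grid origin snaps to the upper-left corner of the raster extent.
    """
    if not layers:
        raise ValueError("at least one raster layer is required")
    if cell_size <= 0:
        raise ValueError(f"cell_size must be > 0, got {cell_size}")
    if not 0 <= min_valid_fraction <= 1:
        raise ValueError(f"min_valid_fraction must be in [0, 1], got {min_valid_fraction}")

    names = list(layers)
    ref = layers[names[0]]
    for name, layer in layers.items():
        if layer.crs != ref.crs:
            raise RasterError(
                f"CRS mismatch: layer {name!r} has {layer.crs}, expected {ref.crs}"
            )
        if layer.shape != ref.shape or layer.transform != ref.transform:
            raise RasterError(
                f"layer {name!r} is not co-registered with {names[0]!r}; "
                "all layers must share one grid"
            )

    nrow_px, ncol_px = ref.shape
    t = ref.transform
    ncols = max(1, math.ceil(ncol_px * t.dx / cell_size - 1e-9))
    nrows = max(1, math.ceil(nrow_px * t.dy / cell_size - 1e-9))

    # bin pixel centers into cells
    xc = (np.arange(ncol_px) + 0.5) * t.dx
    yc = (np.arange(nrow_px) + 0.5) * t.dy
    col_of = np.minimum((xc / cell_size).astype(int), ncols - 1)
    row_of = np.minimum((yc / cell_size).astype(int), nrows - 1)
    cell_idx = (row_of[:, None] * ncols + col_of[None, :]).ravel()
    n_cells = nrows * ncols
    total = np.bincount(cell_idx, minlength=n_cells)

    means: dict[str, np.ndarray] = {}
    valid_in_all = total > 0
    for name, layer in layers.items():
        vals = layer.values.ravel()
        ok = np.isfinite(vals)
        cnt = np.bincount(cell_idx[ok], minlength=n_cells)
        ssum = np.bincount(cell_idx[ok], weights=vals[ok], minlength=n_cells)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(cnt > 0, ssum / np.maximum(cnt, 1), np.nan)
        frac = np.where(total > 0, cnt / np.maximum(total, 1), 0.0)
        layer_ok = (cnt > 0) & (frac >= min_valid_fraction)
        means[name] = np.where(layer_ok, mean, np.nan)
        valid_in_all &= layer_ok

    rows, cols = np.divmod(np.arange(n_cells), ncols)
    keep = valid_in_all
    if not keep.any():
        raise RasterError("no fishnet cell is valid in every layer")
    table = pd.DataFrame(
        {
            "id": np.arange(n_cells)[keep],
            "row": rows[keep],
            "col": cols[keep],
            "u": t.x0 + (cols[keep] + 0.5) * cell_size,
            "v": t.y0 - (rows[keep] + 0.5) * cell_size,
        }
    )
    for name in names:
        table[name] = means[name][keep]
    n_drop = int(n_cells - keep.sum())
    if n_drop:
        logger.info("fishnet: dropped %d of %d cells failing joint validity", n_drop, n_cells)
    return FishnetGrid(
        table=table.reset_index(drop=True),
        cell_size=float(cell_size),
        crs=ref.crs,
        nrows=nrows,
        ncols=ncols,
        origin=(t.x0, t.y0),
    )


def write_table(grid: FishnetGrid, path: str | Path) -> None:
    """Write the cell table as CSV with a JSON metadata sidecar."""
    if grid.n == 0:
        raise ValueError("refusing to write an empty fishnet table")
    path = Path(path)
    grid.table.to_csv(path, index=False)
    meta = {
        "cell_size": grid.cell_size,
        "crs": grid.crs,
        "nrows": grid.nrows,
        "ncols": grid.ncols,
        "origin": list(grid.origin),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_table(path: str | Path) -> FishnetGrid:
    """Read a fishnet table written by :func:`write_table`."""
    path = Path(path)
    table = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        # reconstruct lattice metadata from the table itself
        du = np.diff(np.unique(table["u"]))
        cell = float(du.min()) if du.size else 1.0
        meta = {
            "cell_size": cell,
            "crs": "EPSG:32648",
            "nrows": int(table["row"].max()) + 1,
            "ncols": int(table["col"].max()) + 1,
            "origin": [float(table["u"].min() - cell / 2), float(table["v"].max() + cell / 2)],
        }
    return FishnetGrid(
        table=table,
        cell_size=float(meta["cell_size"]),
        crs=meta["crs"],
        nrows=int(meta["nrows"]),
        ncols=int(meta["ncols"]),
        origin=tuple(meta["origin"]),
    )


def grid_to_geojson(
    grid: FishnetGrid, variables: list[str] | None = None, path: str | Path | None = None
) -> dict:
    """Export cells as square GeoJSON polygons carrying selected variables."""
    variables = variables if variables is not None else grid.variables()
    half = grid.cell_size / 2.0
    features = []
    for rec in grid.table.itertuples(index=False):
        u, v = rec.u, rec.v
        ring = [
            [u - half, v - half],
            [u + half, v - half],
            [u + half, v + half],
            [u - half, v + half],
            [u - half, v - half],
        ]
        props = {"id": int(rec.id)}
        for var in variables:
            val = getattr(rec, var)
            props[var] = None if isinstance(val, float) and np.isnan(val) else val
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    collection = {"type": "FeatureCollection", "crs_name": grid.crs, "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(collection))
    return collection
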