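"""GeoTIFF raster I/O on a projected, axis-aligned grid.

Layers are single-band float rasters on a metric CRS (e.g. a UTM zone).
Missing data are represented as NaN in memory and as an explicit nodata
sentinel on disk (GDAL_NODATA tag). Georeferencing is carried by the
standard GeoTIFF ModelPixelScale / ModelTiepoint / GeoKeyDirectory tags;
rotated (sheared) transforms are not supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import RasterError

logger = logging.getLogger(__name__)

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_MODEL_TRANSFORMATION = 34264
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# GeoKey ids
_GT_MODEL_TYPE = 1024          # 1 = projected, 2 = geographic
_GT_RASTER_TYPE = 1025         # 1 = PixelIsArea
_PROJECTED_CS_TYPE = 3072
_GEOGRAPHIC_TYPE = 2048

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridTransform:
    """Axis-aligned georeference: upper-left corner and pixel sizes.

    ``x0, y0`` locate the outer corner of pixel (0, 0); ``dx, dy`` are the
    positive pixel sizes in meters. Rows advance southwards (decreasing y).
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise RasterError(f"transform {name} must be finite and > 0, got {v}")
        if not (np.isfinite(self.x0) and np.isfinite(self.y0)):
            raise RasterError("transform origin must be finite")

    def pixel_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates for every pixel of ``shape``."""
        nrow, ncol = shape
        x = self.x0 + (np.arange(ncol) + 0.5) * self.dx
        y = self.y0 - (np.arange(nrow) + 0.5) * self.dy
        return np.meshgrid(x, y)


@dataclass
class RasterLayer:
    """A georeferenced 2-D field; missing cells are NaN."""

    values: np.ndarray
    transform: GridTransform
    crs: str = "EPSG:32648"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RasterError(f"raster values must be 2-D, got ndim={self.values.ndim}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def _epsg_code(crs: str) -> int:
    try:
        auth, code = crs.split(":")
    except ValueError:
        raise RasterError(f"CRS must look like 'EPSG:32648', got {crs!r}") from None
    if auth.upper() != "EPSG":
        raise RasterError(f"only EPSG CRS identifiers are supported, got {crs!r}")
    return int(code)


def write_raster(layer: RasterLayer, path: str | Path) -> None:
    """Write a layer as single-band float32 GeoTIFF with geo tags."""
    path = Path(path)
    t = layer.transform
    data = layer.values.astype(np.float32)
    data = np.where(np.isfinite(data), data, np.float32(layer.nodata))
    geokeys = (
        1, 1, 0, 3,
        _GT_MODEL_TYPE, 0, 1, 1,
        _GT_RASTER_TYPE, 0, 1, 1,
        _PROJECTED_CS_TYPE, 0, 1, _epsg_code(layer.crs),
    )
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (t.dx, t.dy, 0.0), True),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0), True),
        (_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys, True),
        (_GDAL_NODATA, "s", 0, repr(float(layer.nodata)), True),
    ]
    try:
        tifffile.imwrite(path, data, extratags=extratags)
    except OSError as exc:
        raise RasterError(f"cannot write raster to {path}: {exc}") from exc


def read_raster(path: str | Path) -> RasterLayer:
    """Read a single-band GeoTIFF written on an axis-aligned projected grid."""
    path = Path(path)
    if not path.exists():
        raise RasterError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) != 1:
            raise RasterError(f"{path}: expected a single band, found {len(tf.pages)} pages")
        page = tf.pages[0]
        arr = page.asarray().astype(float)
        if arr.ndim != 2:
            raise RasterError(f"{path}: expected a single-band 2-D raster")

        if page.tags.get(_MODEL_TRANSFORMATION) is not None:
            m = np.asarray(page.tags[_MODEL_TRANSFORMATION].value, dtype=float).reshape(4, 4)
            if m[0, 1] != 0.0 or m[1, 0] != 0.0:
                raise RasterError(f"{path}: rotated raster transforms are not supported")
            transform = GridTransform(x0=m[0, 3], y0=m[1, 3], dx=m[0, 0], dy=-m[1, 1])
        else:
            scale_tag = page.tags.get(_MODEL_PIXEL_SCALE)
            tie_tag = page.tags.get(_MODEL_TIEPOINT)
            if scale_tag is None or tie_tag is None:
                raise RasterError(f"{path}: missing GeoTIFF georeferencing tags")
            sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
            tie = np.asarray(tie_tag.value, dtype=float)
            # tiepoint maps raster (i, j, k) -> model (x, y, z)
            x0 = tie[3] - tie[0] * sx
            y0 = tie[4] + tie[1] * sy
            transform = GridTransform(x0=x0, y0=y0, dx=sx, dy=sy)

        crs = _read_crs(page, path)
        nodata = _read_nodata(page)

    if nodata is not None:
        arr[arr == nodata] = np.nan
    if not np.isfinite(arr).any():
        logger.warning("%s: raster contains no valid pixels", path)
    return RasterLayer(values=arr, transform=transform, crs=crs,
                       nodata=nodata if nodata is not None else DEFAULT_NODATA)


def _read_crs(page, path: Path) -> str:
    tag = page.tags.get(_GEO_KEY_DIRECTORY)
    if tag is None:
        raise RasterError(f"{path}: no GeoKeyDirectory; cannot determine CRS")
    keys = np.asarray(tag.value, dtype=int).reshape(-1, 4)
    entries = {int(k): int(v) for k, _, _, v in keys[1:]}
    model = entries.get(_GT_MODEL_TYPE)
    if model == 2 or _GEOGRAPHIC_TYPE in entries and _PROJECTED_CS_TYPE not in entries:
        raise RasterError(
            f"{path}: geographic (degree) CRS detected; a projected metric CRS is required"
        )
    code = entries.get(_PROJECTED_CS_TYPE)
    if code is None:
        raise RasterError(f"{path}: GeoKeyDirectory lacks a projected CRS code")
    return f"EPSG:{code}"


def _read_nodata(page) -> float | None:
    tag = page.tags.get(_GDAL_NODATA)
    if tag is None:
        return None
    text = tag.value
    if isinstance(text, bytes):
        text = text.decode("ascii", "ignore")
    text = text.strip().strip("\x00")
    try:
        return float(text)
    except ValueError:
        return None
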