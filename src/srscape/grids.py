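"""Georeferenced raster grids and geographic distance helpers.

A :class:`RasterGrid` is a north-up 2D array with an affine geotransform
(top-left corner origin, signed cell sizes) and a CRS identifier.  Missing
cells are held as NaN in memory; the ``nodata`` sentinel only appears in
files.  GeoTIFF I/O is implemented over :mod:`tifffile` using the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory, GDAL nodata).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile

EARTH_RADIUS_KM = 6371.0088

# GeoTIFF tag ids
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


class RasterError(ValueError):
    """Raised for malformed or inconsistent raster inputs."""


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points in decimal degrees.

    Broadcasts like the underlying numpy ufuncs.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclasses.dataclass
class RasterGrid:
    """North-up georeferenced 2D field.

    Parameters
    ----------
    values : 2D float array; NaN marks missing cells.
    x0, y0 : coordinates of the *top-left corner* of the top-left cell.
    dx : cell width (positive, map units east).
    dy : cell height (negative, map units; row index grows southward).
    crs : CRS identifier, e.g. ``"EPSG:4326"``.
    nodata : sentinel written to / read from files.
    """

    values: np.ndarray
    x0: float
    y0: float
    dx: float
    dy: float
    crs: str = "EPSG:4326"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RasterError("raster values must be a 2D array")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise RasterError("raster must have at least one cell")
        if self.dx == 0 or self.dy == 0:
            raise RasterError("cell sizes must be nonzero")
        if self.dy > 0:
            # normalise to north-up on construction
            self.values = self.values[::-1]
            self.y0 = self.y0 + self.dy * self.values.shape[0]
            self.dy = -self.dy

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer cell edges."""
        ny, nx = self.shape
        ys = sorted((self.y0, self.y0 + self.dy * ny))
        return (self.x0, ys[0], self.x0 + self.dx * nx, ys[1])

    def cell_lons(self) -> np.ndarray:
        nx = self.shape[1]
        return self.x0 + (np.arange(nx) + 0.5) * self.dx

    def cell_lats(self) -> np.ndarray:
        ny = self.shape[0]
        return self.y0 + (np.arange(ny) + 0.5) * self.dy

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (lon, lat) of every cell centre, each shaped like values."""
        lon, lat = np.meshgrid(self.cell_lons(), self.cell_lats())
        return lon, lat

    def contains(self, lon: float, lat: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return (xmin <= lon <= xmax) and (ymin <= lat <= ymax)

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing the point; raises if outside."""
        if not self.contains(lon, lat):
            raise RasterError(f"point ({lon}, {lat}) outside raster extent {self.bounds}")
        j = int((lon - self.x0) / self.dx)
        i = int((lat - self.y0) / self.dy)
        ny, nx = self.shape
        return min(max(i, 0), ny - 1), min(max(j, 0), nx - 1)

    def value_at(self, lon: float, lat: float) -> float:
        i, j = self.index_of(lon, lat)
        return float(self.values[i, j])

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def same_geometry(self, other: "RasterGrid", rtol: float = 1e-9) -> bool:
        return self.shape == other.shape and np.allclose(
            [self.x0, self.y0, self.dx, self.dy],
            [other.x0, other.y0, other.dx, other.dy],
            rtol=rtol, atol=1e-12,
        )

    def like(self, values: np.ndarray) -> "RasterGrid":
        """New grid sharing this geometry."""
        return RasterGrid(values, self.x0, self.y0, self.dx, self.dy, self.crs, self.nodata)


# -- GeoTIFF I/O ------------------------------------------------------------

def _epsg_code(crs: str) -> int | None:
    crs = crs.strip().upper()
    if crs.startswith("EPSG:"):
        return int(crs.split(":", 1)[1])
    return None


def write_raster(grid: RasterGrid, path: str | Path,
                 dtype: type = np.float64) -> Path:
    """Write a GeoTIFF with nodata and georeferencing tags.

    float64 by default so a write-read roundtrip is value-identical; pass
    ``dtype=np.float32`` for half-size files when 7 digits suffice.
    """
    path = Path(path)
    data = grid.values.astype(dtype)
    data = np.where(np.isfinite(data), data, dtype(grid.nodata))
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (abs(grid.dx), abs(grid.dy), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x0, grid.y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    epsg = _epsg_code(grid.crs)
    if epsg is not None:
        # minimal geographic GeoKey directory: model type 2 (geographic), GCS code
        keys = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, epsg)
        extratags.append((_TAG_GEO_KEYS, "H", len(keys), keys))
    tifffile.imwrite(path, data, extratags=extratags)
    return path


def read_raster(path: str | Path, crs: str | None = None) -> RasterGrid:
    """Read a single-band GeoTIFF into a :class:`RasterGrid`.

    ``crs`` overrides/provides the CRS when the file carries no GeoKey
    directory; without either, reading fails.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        tags = {t.code: t.value for t in page.tags.values()}
    if data.ndim != 2:
        raise RasterError(f"{path}: expected a single-band raster")
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise RasterError(f"{path}: no georeferencing (ModelPixelScale/ModelTiepoint) present")
    sx, sy = tags[_TAG_PIXEL_SCALE][0], tags[_TAG_PIXEL_SCALE][1]
    tie = tags[_TAG_TIEPOINT]
    x0 = tie[3] - tie[0] * sx
    y0 = tie[4] + tie[1] * sy
    file_crs = None
    if _TAG_GEO_KEYS in tags:
        keys = tags[_TAG_GEO_KEYS]
        for k in range(4, len(keys), 4):
            if keys[k] == 2048:
                file_crs = f"EPSG:{keys[k + 3]}"
    if file_crs is None and crs is None:
        raise RasterError(
            f"{path}: no CRS found; pass an explicit override, e.g. read_raster(path, crs='EPSG:4326')"
        )
    nodata = DEFAULT_NODATA
    if _TAG_GDAL_NODATA in tags:
        try:
            nodata = float(tags[_TAG_GDAL_NODATA])
        except (TypeError, ValueError):
            pass
    values = np.where(np.isclose(data, nodata, rtol=0, atol=abs(nodata) * 1e-9 + 1e-30), np.nan, data)
    return RasterGrid(values, float(x0), float(y0), float(sx), -float(sy),
                      crs=crs or file_crs, nodata=nodata)
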