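"""Canopy-height-grid raster export/import (GeoTIFF, ESRI ASCII grid).

Grids are written north-up with empty cells encoded as the conventional
-9999 nodata value.  GeoTIFF georeferencing uses the ModelPixelScale and
ModelTiepoint tags plus the GDAL nodata tag, which is what desktop GIS
expects; the ESRI ASCII variant is plain text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .chm import CanopyHeightGrid

__all__ = ["NODATA", "write_chm_raster", "read_chm_raster"]

NODATA = -9999.0

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _to_north_up(grid: CanopyHeightGrid) -> np.ndarray:
    """Grid values as rows of constant y, top row = max y (image order)."""
    arr = np.where(grid.empty, NODATA, grid.values)  # (nx, ny)
    return arr.T[::-1, :].copy()


def _from_north_up(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = img[::-1, :].T.copy()
    empty = values == NODATA
    values = np.where(empty, np.nan, values)
    return values, empty


def write_chm_raster(grid: CanopyHeightGrid, path, fmt: str | None = None
                     ) -> None:
    """Write a canopy height grid as GeoTIFF or ESRI ASCII grid."""
    path = Path(path)
    if grid.values.size == 0:
        raise ValueError("refusing to write an empty grid")
    if fmt is None:
        fmt = "esri_ascii" if path.suffix.lower() in {".asc", ".txt"} \
            else "geotiff"
    if fmt == "geotiff":
        _write_geotiff(grid, path)
    elif fmt == "esri_ascii":
        _write_esri_ascii(grid, path)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")


def read_chm_raster(path) -> CanopyHeightGrid:
    path = Path(path)
    if path.suffix.lower() in {".asc", ".txt"}:
        return _read_esri_ascii(path)
    return _read_geotiff(path)


def _write_geotiff(grid: CanopyHeightGrid, path: Path) -> None:
    img = _to_north_up(grid).astype(np.float64)
    x0, y0 = grid.origin
    ny = grid.values.shape[1]
    y_top = y0 + ny * grid.resolution
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3,
         (grid.resolution, grid.resolution, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y_top, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(int(NODATA))),
    ]
    try:
        tifffile.imwrite(path, img, extratags=extratags)
    except OSError as exc:
        raise IOError(f"cannot write GeoTIFF {path}: {exc}") from exc


def _read_geotiff(path: Path) -> CanopyHeightGrid:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        img = page.asarray().astype(np.float64)
        scale = page.tags[_TAG_MODEL_PIXEL_SCALE].value
        tiepoint = page.tags[_TAG_MODEL_TIEPOINT].value
    resolution = float(scale[0])
    x0 = float(tiepoint[3])
    y_top = float(tiepoint[4])
    values, empty = _from_north_up(img)
    y0 = y_top - img.shape[0] * resolution
    return CanopyHeightGrid(origin=(x0, y0), resolution=resolution,
                            values=values, empty=empty)


def _write_esri_ascii(grid: CanopyHeightGrid, path: Path) -> None:
    img = _to_north_up(grid)
    nrows, ncols = img.shape
    x0, y0 = grid.origin
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {x0:.6f}\n"
        f"yllcorner {y0:.6f}\n"
        f"cellsize {grid.resolution:g}\n"
        f"NODATA_value {int(NODATA)}\n"
    )
    try:
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, img, fmt="%.6f")
    except OSError as exc:
        raise IOError(f"cannot write ESRI ASCII grid {path}: {exc}") from exc


def _read_esri_ascii(path: Path) -> CanopyHeightGrid:
    meta = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        img = np.loadtxt(fh, ndmin=2)
    values, empty = _from_north_up(img)
    return CanopyHeightGrid(
        origin=(meta["xllcorner"], meta["yllcorner"]),
        resolution=meta["cellsize"], values=values, empty=empty,
    )
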