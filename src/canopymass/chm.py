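"""Canopy height model extraction: clip, normalize, grid, fill, summarize.

The plot-level canopy metric is built in five steps.  The vegetation cloud
is clipped to the surveyed plot polygon (boundary-inclusive) with noise
points dropped; each point's height above the TIN terrain is computed, with
negative heights clamped to zero; heights are gridded at 0.01 m resolution
taking the per-cell maximum (a local-maxima canopy surface); cells left
empty by uneven photogrammetric sampling are filled by inverse-distance
weighting over the surrounding 7 x 7 cell window with power 1, in a single
pass (cells with no populated neighbour in that window stay empty); and the
plot mean canopy height is the mean of the non-empty cells of the filled
grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .plots import PlotRecord
from .pointcloud import PointCloud
from .terrain import TerrainModel

__all__ = [
    "ChmConfig", "CanopyHeightGrid", "CanopyMetrics", "EmptyPlotError",
    "clip_to_plot", "height_above_ground", "rasterize_max", "idw_fill",
    "summarize_grid", "compute_plot_metrics",
]


class EmptyPlotError(ValueError):
    """No usable points for a plot: the plot is unreconstructed."""


@dataclass(frozen=True)
class ChmConfig:
    """Gridding parameters for the canopy height model.

    resolution
        Grid cell size in metres (default 0.01).
    idw_window
        Odd side length, in cells, of the centered window searched when
        filling an empty cell (default 7).
    idw_power
        Inverse-distance exponent (default 1).
    negative_clamp
        Clamp negative heights-above-ground to zero (default True).
    mean_over
        ``nonempty_cells``: plot mean over populated cells only (default);
        ``all_cells_empty_as_zero``: unfilled cells count as zero height.
    """

    resolution: float = 0.01
    idw_window: int = 7
    idw_power: float = 1.0
    negative_clamp: bool = True
    mean_over: str = "nonempty_cells"
    terrain_extrapolate: bool = False

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.idw_window < 3 or self.idw_window % 2 == 0:
            raise ValueError("idw_window must be odd and >= 3")
        if self.idw_power <= 0:
            raise ValueError("idw_power must be positive")
        if self.mean_over not in ("nonempty_cells",
                                  "all_cells_empty_as_zero"):
            raise ValueError(f"unknown mean_over policy {self.mean_over!r}")


@dataclass
class CanopyHeightGrid:
    """Raster of local-maxima canopy heights over a plot bounding box.

    ``values[i, j]`` covers x in [x0+i*res, x0+(i+1)*res), y likewise by j;
    ``empty`` marks cells containing no points (and not filled by IDW).
    """

    origin: tuple[float, float]
    resolution: float
    values: np.ndarray
    empty: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.empty = np.asarray(self.empty, dtype=bool)
        if self.values.shape != self.empty.shape:
            raise ValueError("values/empty shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def filled_fraction(self) -> float:
        return float((~self.empty).mean())


@dataclass(frozen=True)
class CanopyMetrics:
    plot_id: str
    mean_height: float       # m
    max_height: float        # m
    filled_fraction: float
    n_points: int


def clip_to_plot(cloud: PointCloud, plot: PlotRecord) -> PointCloud:
    """Points inside or on the plot polygon, noise points removed."""
    if len(cloud) == 0:
        raise EmptyPlotError(f"plot {plot.plot_id!r}: input cloud is empty")
    # cheap bounding-box prefilter before the exact polygon test
    x0, y0, x1, y1 = plot.bbox()
    near = ((cloud.x >= x0) & (cloud.x <= x1)
            & (cloud.y >= y0) & (cloud.y <= y1))
    cloud = cloud.select(near)
    if len(cloud) == 0:
        raise EmptyPlotError(
            f"plot {plot.plot_id!r}: no points inside polygon "
            "(unreconstructed plot)"
        )
    poly = plot.polygon
    shapely.prepare(poly)
    # intersects_xy is boundary-inclusive, matching the rule that surveyed
    # corners delimit (and belong to) the plot
    inside = shapely.intersects_xy(poly, cloud.x, cloud.y)
    keep = inside & ~cloud.noise
    if not keep.any():
        raise EmptyPlotError(
            f"plot {plot.plot_id!r}: no points inside polygon "
            "(unreconstructed plot)"
        )
    return cloud.select(keep)


def height_above_ground(cloud: PointCloud, terrain: TerrainModel,
                        clamp: bool = True,
                        extrapolate: bool = False) -> np.ndarray:
    """Per-point height above the TIN terrain, optionally clamped at zero."""
    ground = terrain.elevation(cloud.x, cloud.y, extrapolate=extrapolate)
    h = cloud.z - ground
    if clamp:
        h = np.maximum(h, 0.0)
    return h


def _grid_geometry(bbox, resolution):
    x0, y0, x1, y1 = bbox
    nx = max(1, int(np.ceil((x1 - x0) / resolution - 1e-9)))
    ny = max(1, int(np.ceil((y1 - y0) / resolution - 1e-9)))
    return x0, y0, nx, ny


def rasterize_max(xy: np.ndarray, heights: np.ndarray, bbox,
                  config: ChmConfig) -> CanopyHeightGrid:
    """Per-cell maximum point height on a regular grid over ``bbox``.

    Cells are half-open intervals; points on the top/right boundary of the
    bounding box are assigned to the last cell so nothing is lost.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    heights = np.asarray(heights, dtype=float).reshape(-1)
    if len(xy) == 0:
        raise EmptyPlotError("no points to rasterize")
    x0, y0, nx, ny = _grid_geometry(bbox, config.resolution)
    ix = np.floor((xy[:, 0] - x0) / config.resolution).astype(np.int64)
    iy = np.floor((xy[:, 1] - y0) / config.resolution).astype(np.int64)
    # upper-boundary points fold into the last cell
    np.clip(ix, 0, nx - 1, out=ix)
    np.clip(iy, 0, ny - 1, out=iy)
    values = np.full((nx, ny), -np.inf)
    np.maximum.at(values, (ix, iy), heights)
    empty = ~np.isfinite(values)
    values[empty] = np.nan
    return CanopyHeightGrid(origin=(x0, y0), resolution=config.resolution,
                            values=values, empty=empty)


def idw_fill(grid: CanopyHeightGrid, config: ChmConfig) -> CanopyHeightGrid:
    """Single-pass inverse-distance-weighted fill of empty cells.

    Each originally-empty cell takes the d^-power weighted mean of the
    originally-populated cells in the centered ``idw_window`` square (the
    cell itself excluded); distances are center-to-center.  Cells with no
    populated cell in the window remain empty.  Populated cells are never
    altered, and fills never cascade (only the pre-fill snapshot serves as
    a source).
    """
    radius = config.idw_window // 2
    src_vals = np.nan_to_num(grid.values, nan=0.0)
    src_mask = (~grid.empty).astype(float)
    nx, ny = grid.shape
    num = np.zeros((nx, ny))
    den = np.zeros((nx, ny))
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            if dx == 0 and dy == 0:
                continue
            w = float(np.hypot(dx, dy)) ** (-config.idw_power)
            # shifted views: contribution of cell (i+dx, j+dy) to cell (i, j)
            xs_t = slice(max(0, -dx), min(nx, nx - dx))
            ys_t = slice(max(0, -dy), min(ny, ny - dy))
            xs_s = slice(max(0, dx), min(nx, nx + dx))
            ys_s = slice(max(0, dy), min(ny, ny + dy))
            num[xs_t, ys_t] += w * src_vals[xs_s, ys_s] * src_mask[xs_s, ys_s]
            den[xs_t, ys_t] += w * src_mask[xs_s, ys_s]
    values = grid.values.copy()
    empty = grid.empty.copy()
    fillable = grid.empty & (den > 0)
    values[fillable] = num[fillable] / den[fillable]
    empty[fillable] = False
    return CanopyHeightGrid(origin=grid.origin, resolution=grid.resolution,
                            values=values, empty=empty)


def summarize_grid(grid: CanopyHeightGrid, config: ChmConfig,
                   plot_id: str = "", n_points: int = 0) -> CanopyMetrics:
    """Plot-level metrics from the (filled) local-maxima grid."""
    populated = grid.values[~grid.empty]
    if populated.size == 0:
        raise EmptyPlotError(f"plot {plot_id!r}: all grid cells empty")
    if config.mean_over == "nonempty_cells":
        mean_h = float(populated.mean())
    else:
        mean_h = float(populated.sum() / grid.values.size)
    return CanopyMetrics(
        plot_id=plot_id,
        mean_height=mean_h,
        max_height=float(populated.max()),
        filled_fraction=grid.filled_fraction,
        n_points=n_points,
    )


def compute_plot_metrics(cloud: PointCloud, plot: PlotRecord,
                         terrain: TerrainModel,
                         config: ChmConfig = ChmConfig(),
                         return_grid: bool = False):
    """Full per-plot chain: clip, normalize, grid, IDW-fill, summarize.

    Raises :class:`EmptyPlotError` when the plot cannot be reconstructed
    (no in-polygon points); callers report such plots rather than abort.
    """
    clipped = clip_to_plot(cloud, plot)
    h = height_above_ground(clipped, terrain, clamp=config.negative_clamp,
                            extrapolate=config.terrain_extrapolate)
    grid = rasterize_max(clipped.xyz[:, :2], h, plot.bbox(), config)
    grid = idw_fill(grid, config)
    metrics = summarize_grid(grid, config, plot_id=plot.plot_id,
                             n_points=len(clipped))
    if return_grid:
        return metrics, grid
    return metrics
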