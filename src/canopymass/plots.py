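"""Harvest-plot records: corner geometry, biomass and survey covariates.

A harvest plot is a small polygon (protocol minimum 0.5 x 0.5 m) whose
corners were surveyed with a high-precision GNSS, then clipped from the
vegetation and weighed dry.  Each record carries the corner coordinates with
ground elevations, dry aboveground biomass, taxon and plant functional type,
and the survey covariates used by the environmental-effect models (wind
speed, timestamp/location for sun elevation, sky code).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = ["PlotRecord", "load_plot_table", "write_plot_table",
            "shoelace_area", "PFTS"]

PFTS = ("fern", "forb", "graminoid", "shrub", "tree", "succulent")

MIN_PLOT_SIDE = 0.5  # m, protocol minimum plot dimension


def shoelace_area(xy: np.ndarray) -> float:
    """Planar polygon area by the shoelace formula (vertices ordered)."""
    xy = np.asarray(xy, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class PlotRecord:
    plot_id: str
    corners: np.ndarray           # (k, 3): x, y, z_ground in metres
    biomass: float                # dry AGB, g (whole plot)
    species: str = ""
    pft: str = ""
    survey_id: str = ""
    wind_speed: float = np.nan    # m s^-1, ~2 m above ground
    timestamp: str = ""           # ISO 8601, UTC
    latitude: float = np.nan
    longitude: float = np.nan
    sky_code: int = -1            # ordinal 0-10; >=6 means sun obscured
    area: float = field(init=False)

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, dtype=float).reshape(-1, 3)
        if len(self.corners) < 3:
            raise ValueError(
                f"plot {self.plot_id!r}: needs >=3 corners, "
                f"got {len(self.corners)}"
            )
        if not np.isfinite(self.corners).all():
            raise ValueError(f"plot {self.plot_id!r}: non-finite corner")
        self.area = shoelace_area(self.corners[:, :2])
        if self.area <= 0:
            raise ValueError(
                f"plot {self.plot_id!r}: corners are collinear or "
                "degenerate (zero area)"
            )
        poly = self.polygon
        if not poly.is_valid:
            raise ValueError(
                f"plot {self.plot_id!r}: corner polygon is not simple"
            )
        if self.biomass < 0:
            raise ValueError(f"plot {self.plot_id!r}: negative biomass")
        if self.pft and self.pft not in PFTS:
            raise ValueError(
                f"plot {self.plot_id!r}: unknown PFT {self.pft!r}"
            )
        dx = float(np.ptp(self.corners[:, 0]))
        dy = float(np.ptp(self.corners[:, 1]))
        if dx < MIN_PLOT_SIDE or dy < MIN_PLOT_SIDE:
            warnings.warn(
                f"plot {self.plot_id!r}: bounding box {dx:.2f} x {dy:.2f} m "
                f"is below the {MIN_PLOT_SIDE} x {MIN_PLOT_SIDE} m protocol "
                "minimum",
                stacklevel=2,
            )

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.corners[:, :2])

    @property
    def biomass_per_area(self) -> float:
        """Dry AGB per unit ground area, g m^-2."""
        return self.biomass / self.area

    @property
    def cloudy(self) -> bool:
        """Sun obscured: sky code >= 6."""
        return self.sky_code >= 6

    def bbox(self) -> tuple[float, float, float, float]:
        x, y = self.corners[:, 0], self.corners[:, 1]
        return float(x.min()), float(y.min()), float(x.max()), float(y.max())


_ATTR_COLUMNS = {
    "biomass_g": ("biomass", float),
    "species": ("species", str),
    "pft": ("pft", str),
    "survey_id": ("survey_id", str),
    "wind_speed_ms": ("wind_speed", float),
    "timestamp_utc": ("timestamp", str),
    "latitude_deg": ("latitude", float),
    "longitude_deg": ("longitude", float),
    "sky_code": ("sky_code", int),
}


def load_plot_table(corners_path, attributes_path=None) -> list[PlotRecord]:
    """Load plot records from CSV corner+attribute tables or a GeoJSON.

    The CSV convention is one row per corner (``plot_id, corner_index, x, y,
    z``) joined on ``plot_id`` to an attribute table; a GeoJSON of polygon
    features carries attributes as feature properties and ground elevations
    as the polygon's third coordinate.
    """
    corners_path = Path(corners_path)
    if corners_path.suffix.lower() in {".geojson", ".json"}:
        return _load_geojson(corners_path)
    corners = pd.read_csv(corners_path, comment="#")
    need = {"plot_id", "corner_index", "x", "y", "z"}
    if not need.issubset(corners.columns):
        raise ValueError(
            f"corner table lacks columns {sorted(need - set(corners.columns))}"
        )
    attrs = None
    if attributes_path is not None:
        attrs = pd.read_csv(attributes_path, comment="#")
        if attrs["plot_id"].duplicated().any():
            dup = attrs.loc[attrs["plot_id"].duplicated(), "plot_id"].tolist()
            raise ValueError(f"duplicate plot_id in attribute table: {dup}")
        attrs = attrs.set_index("plot_id")
    records = []
    seen: set[str] = set()
    for plot_id, grp in corners.groupby("plot_id", sort=False):
        plot_id = str(plot_id)
        if plot_id in seen:
            raise ValueError(f"duplicate plot_id {plot_id!r} in corner table")
        seen.add(plot_id)
        grp = grp.sort_values("corner_index")
        xyz = grp[["x", "y", "z"]].to_numpy(float)
        kwargs = {}
        if attrs is not None:
            if plot_id not in attrs.index:
                raise ValueError(f"plot {plot_id!r} missing from attributes")
            row = attrs.loc[plot_id]
            for col, (name, cast) in _ATTR_COLUMNS.items():
                if col in row.index and not pd.isna(row[col]):
                    kwargs[name] = cast(row[col])
        records.append(
            PlotRecord(plot_id=plot_id, corners=xyz,
                       biomass=kwargs.pop("biomass", 0.0), **kwargs)
        )
    return records


def _load_geojson(path: Path) -> list[PlotRecord]:
    data = json.loads(Path(path).read_text())
    records = []
    seen: set[str] = set()
    for feat in data.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ValueError("GeoJSON plot features must be Polygons")
        ring = geom["coordinates"][0]
        if len(ring) > 1 and ring[0] == ring[-1]:
            ring = ring[:-1]  # drop closing vertex
        corners = np.asarray(ring, dtype=float)
        if corners.shape[1] == 2:
            raise ValueError(
                "GeoJSON plot polygons must carry ground elevation as the "
                "third coordinate"
            )
        props = dict(feat.get("properties", {}))
        plot_id = str(props.pop("plot_id"))
        if plot_id in seen:
            raise ValueError(f"duplicate plot_id {plot_id!r} in GeoJSON")
        seen.add(plot_id)
        kwargs = {}
        for col, (name, cast) in _ATTR_COLUMNS.items():
            if col in props and props[col] is not None:
                kwargs[name] = cast(props[col])
        records.append(
            PlotRecord(plot_id=plot_id, corners=corners,
                       biomass=kwargs.pop("biomass", 0.0), **kwargs)
        )
    return records


def write_plot_table(records: Sequence[PlotRecord], corners_path,
                     attributes_path) -> None:
    """Write the CSV corner + attribute tables `load_plot_table` reads."""
    corner_rows = []
    attr_rows = []
    for rec in records:
        for i, (x, y, z) in enumerate(rec.corners):
            corner_rows.append(
                {"plot_id": rec.plot_id, "corner_index": i,
                 "x": x, "y": y, "z": z}
            )
        attr_rows.append(
            {
                "plot_id": rec.plot_id,
                "biomass_g": rec.biomass,
                "species": rec.species,
                "pft": rec.pft,
                "survey_id": rec.survey_id,
                "wind_speed_ms": rec.wind_speed,
                "timestamp_utc": rec.timestamp,
                "latitude_deg": rec.latitude,
                "longitude_deg": rec.longitude,
                "sky_code": rec.sky_code,
            }
        )
    pd.DataFrame(corner_rows).to_csv(corners_path, index=False)
    pd.DataFrame(attr_rows).to_csv(attributes_path, index=False)
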