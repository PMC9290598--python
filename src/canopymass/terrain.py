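"""Triangulated terrain model over GNSS-surveyed plot-corner points.

The digital terrain model is a TIN: a Delaunay triangulation of the corner
points' planar projections, with the surveyed ground elevation carried on
each vertex and queried by barycentric-linear interpolation inside the
containing triangle.  Built per survey from the union of all plot corners by
default, so each plot's interior is supported by neighbouring corners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

__all__ = ["TerrainModel", "build_terrain", "TerrainError"]


class TerrainError(ValueError):
    """Degenerate or inconsistent terrain input."""


@dataclass
class TerrainModel:
    vertices: np.ndarray      # (n, 3)
    triangles: np.ndarray     # (m, 3) vertex indices
    _tri: Delaunay

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def elevation(self, x, y, extrapolate: bool = False) -> np.ndarray:
        """Interpolated ground elevation at planar query points (metres).

        Queries outside the convex hull raise unless ``extrapolate`` is set,
        in which case the nearest simplex's plane is extended outward.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        pts = np.column_stack([x, y])
        simplex = self._tri.find_simplex(pts)
        outside = simplex < 0
        if outside.any():
            if not extrapolate:
                i = int(np.flatnonzero(outside)[0])
                raise TerrainError(
                    f"query point ({x[i]:.3f}, {y[i]:.3f}) lies outside the "
                    "terrain convex hull"
                )
            simplex = simplex.copy()
            simplex[outside] = self._nearest_simplex(pts[outside])
        # barycentric coordinates within the assigned simplex
        T = self._tri.transform[simplex]  # (k, 3, 2) for 2-D
        r = pts - T[:, 2, :]
        bc = np.einsum("kij,kj->ki", T[:, :2, :], r)
        bary = np.column_stack([bc, 1.0 - bc.sum(axis=1)])
        zvals = self.vertices[self._tri.simplices[simplex], 2]
        return np.einsum("ki,ki->k", bary, zvals)

    def _nearest_simplex(self, pts: np.ndarray) -> np.ndarray:
        """Simplex whose centroid is closest to each (outside) point."""
        centroids = self.vertices[self._tri.simplices, :2].mean(axis=1)
        d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def to_ply(self, path) -> None:
        """Export the TIN as an ASCII PLY mesh for inspection."""
        v, f = self.vertices, self.triangles
        lines = [
            "ply", "format ascii 1.0",
            f"element vertex {len(v)}",
            "property double x", "property double y", "property double z",
            f"element face {len(f)}",
            "property list uchar int vertex_indices", "end_header",
        ]
        lines += [f"{a:.9f} {b:.9f} {c:.9f}" for a, b, c in v]
        lines += [f"3 {i} {j} {k}" for i, j, k in f]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def build_terrain(corner_points) -> TerrainModel:
    """Delaunay-triangulate corner points into a queryable terrain model.

    Duplicate planar locations with equal elevation are merged; duplicates
    with conflicting elevations are an error (they would make the surface
    multivalued).  Input order does not affect the result: points are sorted
    before triangulating so co-circular ties break deterministically.
    """
    pts = np.asarray(corner_points, dtype=float).reshape(-1, 3)
    if not np.isfinite(pts).all():
        raise TerrainError("non-finite corner coordinate")
    # deduplicate identical (x, y); conflicting z is an error
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    keep = [0]
    offenders = []
    for i in range(1, len(pts)):
        if pts[i, 0] == pts[keep[-1], 0] and pts[i, 1] == pts[keep[-1], 1]:
            if abs(pts[i, 2] - pts[keep[-1], 2]) > 1e-9:
                offenders.append((tuple(pts[keep[-1]]), tuple(pts[i])))
        else:
            keep.append(i)
    if offenders:
        raise TerrainError(
            "duplicate planar corner locations with conflicting elevations: "
            f"{offenders}"
        )
    pts = pts[keep]
    if len(pts) < 3:
        raise TerrainError(
            f"terrain needs >=3 distinct corner points, got {len(pts)}"
        )
    try:
        tri = Delaunay(pts[:, :2])
    except Exception as exc:  # QhullError on collinear input
        raise TerrainError(f"cannot triangulate corner points: {exc}") from exc
    if tri.simplices.size == 0:
        raise TerrainError("corner points are collinear; no triangulation")
    return TerrainModel(vertices=pts, triangles=tri.simplices.copy(),
                        _tri=tri)
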