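"""Convex-hull territory metrics: 2D hulls with Feret calipers, 3D hulls.

The Feret maximum/minimum are the largest and smallest caliper widths of a
projected point set; both are computed exactly on the convex hull (Feret
minimum by rotating calipers over hull edges, not by angular sampling).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .morphology import DegenerateGeometryError


@dataclass(frozen=True)
class Hull2D:
    """Convex hull of projected points: vertices are CCW (m, 2)."""

    vertices: np.ndarray
    area: float
    perimeter: float
    feret_max: float
    feret_min: float

    def wkt(self) -> str:
        from shapely.geometry import Polygon

        return Polygon(self.vertices).wkt


@dataclass(frozen=True)
class Hull3D:
    volume: float
    surface_area: float
    n_vertices: int


def feret_diameters(hull_vertices: np.ndarray) -> tuple[float, float]:
    """Exact Feret (caliper) maximum and minimum of a convex polygon.

    Maximum: largest pairwise vertex distance.  Minimum: for each hull edge,
    the farthest vertex distance from the edge's supporting line; the minimum
    of these widths over all edges (rotating calipers).
    """
    v = np.asarray(hull_vertices, dtype=float)
    m = len(v)
    if m < 2:
        raise DegenerateGeometryError("Feret diameters need >= 2 hull vertices")
    diff = v[:, None, :] - v[None, :, :]
    fmax = float(np.sqrt((diff**2).sum(-1)).max())
    if m == 2:
        return fmax, 0.0
    fmin = np.inf
    for i in range(m):
        a = v[i]
        b = v[(i + 1) % m]
        e = b - a
        norm = np.hypot(*e)
        if norm == 0:
            continue
        u = e / norm
        rel = v - a
        width = np.abs(u[0] * rel[:, 1] - u[1] * rel[:, 0]).max()
        fmin = min(fmin, float(width))
    return fmax, float(fmin)


def convex_hull_2d(points: np.ndarray) -> Hull2D:
    """2D convex hull with area, perimeter and Feret calipers.

    ``points`` is an (n, 2) array of plane coordinates (already projected).
    Raises DegenerateGeometryError for collinear input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("convex_hull_2d expects (n, 2) plane coordinates")
    if len(pts) < 3:
        raise DegenerateGeometryError("need >= 3 points for a 2D hull")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate 2D hull: {exc}") from exc
    verts = pts[hull.vertices]  # CCW for 2D
    fmax, fmin = feret_diameters(verts)
    # scipy 2D convention: .volume is the area, .area is the perimeter
    return Hull2D(
        vertices=verts,
        area=float(hull.volume),
        perimeter=float(hull.area),
        feret_max=fmax,
        feret_min=fmin,
    )


def convex_hull_3d(points: np.ndarray) -> Hull3D:
    """3D convex hull volume and surface area.

    Raises DegenerateGeometryError for coplanar input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("convex_hull_3d expects (n, 3) coordinates")
    if len(pts) < 4:
        raise DegenerateGeometryError("need >= 4 points for a 3D hull")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate 3D hull: {exc}") from exc
    return Hull3D(volume=float(hull.volume), surface_area=float(hull.area), n_vertices=len(hull.vertices))
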