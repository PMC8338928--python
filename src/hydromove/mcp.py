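"""Minimum convex polygons with centroid-distance peeling.

The 95% MCP removes the 5% of points farthest from the arithmetic-mean
centroid before taking the convex hull, which strips occasional excursions
from the residence polygon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint
from shapely.geometry.base import BaseGeometry


@dataclass
class Mcp:
    """Peeled convex hull of a planar point set.

    ``degenerate`` is set when fewer than 3 distinct points survive peeling
    (hull collapses to a point or segment); overlap tests should then buffer
    the geometry by one grid cell.
    """

    polygon: BaseGeometry
    degenerate: bool
    n_points: int
    n_used: int
    retained: np.ndarray

    @property
    def area_km2(self) -> float:
        return self.polygon.area / 1e6


def mcp_95(points: np.ndarray, retain: float = 0.95) -> Mcp:
    """Minimum convex polygon retaining a fraction of points.

    Peels ``floor((1 - retain) * n)`` points farthest from the mean centroid
    (stable sort, so ties keep input order) and returns the convex hull of
    the remainder.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(pts)
    if n == 0:
        raise ValueError("empty point set")
    if not 0 < retain <= 1:
        raise ValueError("retain must be in (0, 1]")
    n_peel = int(np.floor((1.0 - retain) * n))
    centroid = pts.mean(axis=0)
    dist = np.hypot(*(pts - centroid).T)
    order = np.argsort(dist, kind="stable")
    kept_idx = np.sort(order[: n - n_peel])
    kept = pts[kept_idx]
    hull = MultiPoint(kept).convex_hull
    degenerate = hull.geom_type != "Polygon" or len(np.unique(kept, axis=0)) < 3
    return Mcp(polygon=hull, degenerate=degenerate, n_points=n, n_used=len(kept), retained=kept)


def mcps_overlap(a: Mcp, b: Mcp, buffer_m: float = 500.0) -> bool:
    """Binary overlap rule for consecutive residence areas.

    Non-empty intersection, boundary touch included.  Degenerate geometries
    (points/segments) are buffered by one grid cell so the test stays
    deterministic.
    """
    ga = a.polygon.buffer(buffer_m) if a.degenerate else a.polygon
    gb = b.polygon.buffer(buffer_m) if b.degenerate else b.polygon
    return bool(ga.intersects(gb))
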