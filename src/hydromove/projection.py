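"""Local planar projection for convex-hull and raster work.

Hulls, polygon intersection and kernel smoothing are planar operations, so
geographic fixes are projected with a local equirectangular projection about
a reference point.  At the spatial scales of residence areas and home ranges
(tens of kilometres) the distortion of this projection is far below the GPS
fix error, and it keeps the forward/inverse maps trivially invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Mean Earth radius (IUGG), kilometres.
EARTH_RADIUS_KM = 6371.0088
EARTH_RADIUS_M = EARTH_RADIUS_KM * 1000.0


@dataclass(frozen=True)
class LocalProjection:
    """Equirectangular projection centred on (``lon0``, ``lat0``).

    x = R cos(lat0) (lon − lon0), y = R (lat − lat0), both in metres.
    """

    lon0: float
    lat0: float

    def to_planar(self, lon, lat) -> np.ndarray:
        """Project lon/lat degrees to an ``(n, 2)`` array of metres."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        x = EARTH_RADIUS_M * np.cos(np.radians(self.lat0)) * np.radians(lon - self.lon0)
        y = EARTH_RADIUS_M * np.radians(lat - self.lat0)
        return np.column_stack([x, y])

    def to_lonlat(self, x, y) -> np.ndarray:
        """Inverse of :meth:`to_planar`; returns an ``(n, 2)`` lon/lat array."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        lon = self.lon0 + np.degrees(x / (EARTH_RADIUS_M * np.cos(np.radians(self.lat0))))
        lat = self.lat0 + np.degrees(y / EARTH_RADIUS_M)
        return np.column_stack([lon, lat])

    @classmethod
    def for_points(cls, lon, lat) -> "LocalProjection":
        """Projection centred on the mean coordinate of a point set."""
        return cls(lon0=float(np.mean(lon)), lat0=float(np.mean(lat)))
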