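"""Geodesic primitives shared across the package.

All public coordinates are WGS84 decimal degrees; all distances are metres on
a sphere of mean radius 6,371,008.8 m (haversine).  City-scale work happens in
a local equirectangular projection anchored at a declared reference point:
at the <100 km extents this package targets, the projection error against the
haversine distance is a small fraction of a percent, which the path-crossing
index absorbs by inflating its query radius before exact refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.ops import transform as _shapely_transform

EARTH_RADIUS_M = 6_371_008.8  # WGS84 mean radius


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres between points in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards against rounding for antipodal / identical points
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass(frozen=True)
class LocalProjection:
    """Equirectangular projection anchored at (anchor_lat, anchor_lon).

    x (east, m) = R * cos(anchor_lat) * dlon ; y (north, m) = R * dlat.
    The inverse is exact for the forward map, so round trips are lossless up
    to float precision.
    """

    anchor_lat: float
    anchor_lon: float

    @property
    def _coslat(self) -> float:
        return float(np.cos(np.radians(self.anchor_lat)))

    def to_xy(self, lat, lon):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        x = np.radians(lon - self.anchor_lon) * EARTH_RADIUS_M * self._coslat
        y = np.radians(lat - self.anchor_lat) * EARTH_RADIUS_M
        return x, y

    def to_latlon(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lat = self.anchor_lat + np.degrees(y / EARTH_RADIUS_M)
        lon = self.anchor_lon + np.degrees(x / (EARTH_RADIUS_M * self._coslat))
        return lat, lon

    def project_geometry(self, geom):
        """Project a shapely geometry from (lon, lat) to local (x, y) metres."""

        def fwd(lon, lat):
            x, y = self.to_xy(np.asarray(lat), np.asarray(lon))
            return x, y

        return _shapely_transform(fwd, geom)

    def unproject_geometry(self, geom):
        """Inverse of :meth:`project_geometry`."""

        def inv(x, y):
            lat, lon = self.to_latlon(np.asarray(x), np.asarray(y))
            return lon, lat

        return _shapely_transform(inv, geom)


def projection_for(lats, lons) -> LocalProjection:
    """Projection anchored at the centroid of a point cloud."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if lats.size == 0:
        return LocalProjection(0.0, 0.0)
    return LocalProjection(float(np.mean(lats)), float(np.mean(lons)))


def geometry_anchor(geoms) -> LocalProjection:
    """Projection anchored at the centroid of a collection of geometries."""
    union = shapely.union_all(list(geoms))
    c = union.centroid
    return LocalProjection(c.y, c.x)
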