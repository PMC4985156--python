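"""Spherical geometry helpers for colony-centred track analysis.

All distances are great-circle distances on a sphere of mean radius
6371.0088 km; at the <100 km scale of a central-place forager's trips the
ellipsoidal correction is well below the GPS error budget.

A local azimuthal-equidistant plane centred on the colony carries the
simulation and the gridding: a point at great-circle distance ``d`` and
initial bearing ``theta`` from the centre maps to ``(d sin theta,
d cos theta)`` in km, so distances *from the centre* are exact and local
distances are accurate to O((d/R)^2).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points in decimal degrees.

    Accepts scalars or numpy arrays (broadcast).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_rad(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing (radians clockwise from north)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.arctan2(y, x)


def destination_point(lon, lat, bearing_rad, distance_km):
    """Point reached from (lon, lat) on the given bearing after distance_km."""
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    theta = np.asarray(bearing_rad, dtype=float)
    lat2 = np.arcsin(np.sin(lat1) * np.cos(delta)
                     + np.cos(lat1) * np.sin(delta) * np.cos(theta))
    lon2 = lon1 + np.arctan2(np.sin(theta) * np.sin(delta) * np.cos(lat1),
                             np.cos(delta) - np.sin(lat1) * np.sin(lat2))
    return np.degrees(lon2), np.degrees(lat2)


class LocalProjection:
    """Azimuthal-equidistant plane (km) centred on a reference lon/lat.

    ``forward`` maps lon/lat to (x east, y north) km; ``inverse`` maps back.
    Exact for distance and bearing from the centre.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)

    def forward(self, lon, lat):
        d = haversine_km(self.lon0, self.lat0, lon, lat)
        theta = initial_bearing_rad(self.lon0, self.lat0, lon, lat)
        return d * np.sin(theta), d * np.cos(theta)

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        d = np.hypot(x, y)
        theta = np.arctan2(x, y)
        return destination_point(self.lon0, self.lat0, theta, d)
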