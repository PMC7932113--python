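"""Map projection and great-circle utilities.

All movement modelling and area computation happens in a Lambert azimuthal
equal-area (LAEA) plane centred on the study region (default 54.01°S,
36.3°W, i.e. just east of South Georgia), with coordinates in kilometres.
A spherical Earth of radius 6371 km is used throughout; at the study
scale (hundreds of km) the spherical/ellipsoidal difference is far below
the ARGOS location error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass(frozen=True)
class LambertAzimuthalEqualArea:
    """Spherical Lambert azimuthal equal-area projection (km units)."""

    lon0: float = -36.3
    lat0: float = -54.01
    radius_km: float = EARTH_RADIUS_KM

    def forward(self, lon, lat):
        """Project (lon, lat) degrees -> (x, y) km."""
        lam = np.radians(np.asarray(lon, dtype=float) - self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        phi0 = np.radians(self.lat0)
        denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
        k = np.sqrt(2.0 / denom)
        x = self.radius_km * k * np.cos(phi) * np.sin(lam)
        y = self.radius_km * k * (np.cos(phi0) * np.sin(phi)
                                  - np.sin(phi0) * np.cos(phi) * np.cos(lam))
        return x, y

    def inverse(self, x, y):
        """Unproject (x, y) km -> (lon, lat) degrees."""
        x = np.asarray(x, dtype=float) / self.radius_km
        y = np.asarray(y, dtype=float) / self.radius_km
        phi0 = np.radians(self.lat0)
        rho = np.hypot(x, y)
        # c is the angular distance from the projection centre
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(
                rho > 0,
                np.arcsin(np.clip(np.cos(c) * np.sin(phi0)
                                  + np.where(rho > 0, y * np.sin(c) / np.where(rho > 0, rho, 1.0), 0.0)
                                  * np.cos(phi0), -1.0, 1.0)),
                phi0,
            )
            lam = np.where(
                rho > 0,
                np.arctan2(x * np.sin(c),
                           rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c)),
                0.0,
            )
        lon = self.lon0 + np.degrees(lam)
        lat = np.degrees(phi)
        return lon, lat


#: Projection used by the whole pipeline unless a caller overrides it.
DEFAULT_PROJECTION = LambertAzimuthalEqualArea()
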