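"""Spherical geodesy and circular statistics.

Shared conventions for every track and wind computation in the package:

* the Earth is a sphere of radius 6371.0 km — at the <= 100 km scales of
  regional homing flights the ellipsoidal correction is below 0.5 %;
* bearings/azimuths are degrees clockwise from true north in [0, 360);
  "west" is 270 degrees;
* longitudes are normalised into (-180, 180].
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0
WEST_DEG = 270.0

#: resultant lengths below this are treated as a fully symmetric sample,
#: whose mean direction is undefined
_R_UNDEFINED = 1e-12


class CoincidentPointsError(ValueError):
    """Bearing requested between two identical points."""


def normalize_lon(lon: float) -> float:
    """Wrap a longitude into (-180, 180]."""
    lon = math.fmod(math.fmod(lon, 360.0) + 360.0, 360.0)
    return lon - 360.0 if lon > 180.0 else lon


@dataclass(frozen=True)
class GeoPoint:
    """A position on the sphere, degrees. ``lat`` in [-90, 90]."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        object.__setattr__(self, "lon", normalize_lon(self.lon))


@dataclass(frozen=True)
class MeanVector:
    """Circular mean direction (degrees from north) and resultant length r.

    When the sample is fully symmetric the resultant vanishes: ``r`` is 0
    and ``direction`` is NaN with :attr:`defined` False, rather than an
    arbitrary angle.
    """

    direction: float
    r: float

    @property
    def defined(self) -> bool:
        return self.r > _R_UNDEFINED


# ---------------------------------------------------------------------------
# array kernels (accept scalars or numpy arrays, degrees in / degrees-km out)

def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between coordinate arrays."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def bearing_deg(lat1, lon1, lat2, lon2):
    """Forward azimuth (degrees clockwise from north) between coordinate arrays.

    Coincident points yield an ill-conditioned atan2(0, 0) = 0; callers that
    need a hard error use :func:`initial_bearing`.
    """
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    b = np.degrees(np.arctan2(y, x)) % 360.0
    return np.where(b >= 360.0, 0.0, b)  # guard the 360.0 float wraparound


# ---------------------------------------------------------------------------
# GeoPoint API

def haversine_distance(p: GeoPoint, q: GeoPoint) -> float:
    """Great-circle distance p->q in kilometres."""
    return float(haversine_km(p.lat, p.lon, q.lat, q.lon))


def initial_bearing(p: GeoPoint, q: GeoPoint) -> float:
    """Forward azimuth of the great circle p->q, degrees in [0, 360)."""
    if p.lat == q.lat and p.lon == q.lon:
        raise CoincidentPointsError("bearing undefined between coincident points")
    return float(bearing_deg(p.lat, p.lon, q.lat, q.lon))


def destination_point(p: GeoPoint, bearing: float, distance_km: float) -> GeoPoint:
    """Point reached travelling ``distance_km`` along the great circle from ``p``."""
    if distance_km < 0:
        raise ValueError("distance must be non-negative")
    if distance_km == 0:
        return p
    delta = distance_km / EARTH_RADIUS_KM
    theta = math.radians(bearing)
    phi1 = math.radians(p.lat)
    lam1 = math.radians(p.lon)
    sin_phi2 = math.sin(phi1) * math.cos(delta) + math.cos(phi1) * math.sin(delta) * math.cos(theta)
    phi2 = math.asin(max(-1.0, min(1.0, sin_phi2)))
    lam2 = lam1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * sin_phi2,
    )
    return GeoPoint(math.degrees(phi2), math.degrees(lam2))


def circular_mean(angles_deg, weights=None) -> MeanVector:
    """Weighted circular mean of compass angles.

    ``r`` is the resultant length divided by the total weight, so it lies
    in [0, 1]; 1 means perfectly aligned headings, 0 a symmetric scatter.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circular_mean of empty sample")
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != a.shape:
            raise ValueError("weights must match angles in length")
        if (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be non-negative and not all zero")
    c = float(np.sum(w * np.cos(a))) / float(w.sum())
    s = float(np.sum(w * np.sin(a))) / float(w.sum())
    r = math.hypot(c, s)
    if r <= _R_UNDEFINED:
        return MeanVector(direction=math.nan, r=0.0)
    direction = math.degrees(math.atan2(s, c)) % 360.0
    if direction >= 360.0:
        direction = 0.0
    return MeanVector(direction=direction, r=min(r, 1.0))


def angular_difference(x, y, signed: bool = False):
    """Difference between compass angles x and y.

    Signed: wrap(x - y) into (-180, 180]. Absolute: |wrap(x - y)| in [0, 180].
    Works elementwise on arrays.
    """
    d = (np.asarray(x, dtype=float) - np.asarray(y, dtype=float)) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    out = d if signed else np.abs(d)
    return float(out) if out.ndim == 0 else out
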