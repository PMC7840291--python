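"""Spherical geometry for GPS trajectories.

Distances use the haversine great-circle formula on a sphere of mean radius
6371.0088 km; at the neighbourhood-to-city scales relevant to life-space
mobility the difference from a full ellipsoidal geodesic is far below GPS
noise.  Planar work (ellipse fitting, k-means clustering) goes through an
azimuthal-equidistant projection about a local origin, which preserves
distance and bearing from the origin exactly and distorts distances between
non-origin points by less than 0.5% within 100 km of the origin.
"""

from __future__ import annotations

import warnings

import numpy as np

EARTH_RADIUS_KM = 6371.0088

#: beyond this distance from the projection origin the local-plane
#: approximation is no longer trustworthy for pairwise geometry
MAX_PROJECT_KM = 500.0


def _validated_radians(*vals):
    out = []
    for v in vals:
        a = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite coordinate")
        out.append(np.radians(a))
    return out


def geodesic_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.  Symmetric, and zero exactly
    when the two points coincide.
    """
    for lat in (lat1, lat2):
        if np.any(np.abs(np.asarray(lat, dtype=float)) > 90.0):
            raise ValueError("latitude outside [-90, 90]")
    p1, l1, p2, l2 = _validated_radians(lat1, lon1, lat2, lon2)
    h = (
        np.sin((p2 - p1) / 2.0) ** 2
        + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2.0) ** 2
    )
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_geodesic_km(lats, lons):
    """Full matrix of great-circle distances among a set of points."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    return geodesic_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])


def initial_bearing_rad(lat1, lon1, lat2, lon2):
    """Forward azimuth from point 1 to point 2, radians clockwise from north."""
    p1, l1, p2, l2 = _validated_radians(lat1, lon1, lat2, lon2)
    dl = l2 - l1
    x = np.sin(dl) * np.cos(p2)
    y = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl)
    return np.arctan2(x, y)


def destination_point(lat, lon, bearing_rad, distance_km):
    """Point reached travelling ``distance_km`` along ``bearing_rad`` on the sphere."""
    (p1, l1) = _validated_radians(lat, lon)
    b = np.asarray(bearing_rad, dtype=float)
    d = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    p2 = np.arcsin(np.sin(p1) * np.cos(d) + np.cos(p1) * np.sin(d) * np.cos(b))
    l2 = l1 + np.arctan2(
        np.sin(b) * np.sin(d) * np.cos(p1),
        np.cos(d) - np.sin(p1) * np.sin(p2),
    )
    lat2 = np.degrees(p2)
    lon2 = (np.degrees(l2) + 180.0) % 360.0 - 180.0
    return lat2, lon2


def project_local(lats, lons, origin_lat, origin_lon):
    """Project lat/lon onto a local plane centred at ``origin`` (km east, km north).

    Azimuthal equidistant: the planar norm of a projected point equals its
    great-circle distance from the origin exactly.  Points more than
    ``MAX_PROJECT_KM`` from the origin are flagged with a warning.
    """
    d = geodesic_km(origin_lat, origin_lon, lats, lons)
    if np.any(np.asarray(d) > MAX_PROJECT_KM):
        warnings.warn(
            f"projecting points more than {MAX_PROJECT_KM:.0f} km from origin; "
            "planar geometry may be distorted",
            stacklevel=2,
        )
    theta = initial_bearing_rad(origin_lat, origin_lon, lats, lons)
    return d * np.sin(theta), d * np.cos(theta)


def unproject_local(x, y, origin_lat, origin_lon):
    """Inverse of :func:`project_local`: planar km offsets back to lat/lon."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = np.hypot(x, y)
    theta = np.arctan2(x, y)
    return destination_point(origin_lat, origin_lon, theta, d)
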