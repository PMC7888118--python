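"""Spherical geodesy on the authalic Earth radius.

All distances are kilometres, all angles radians unless noted. Bearings are
compass bearings: measured clockwise from true north, so east = +pi/2.
One convention is used at every spatial scale in the package, from ~1 km
(terrestrial step lengths) to ~1000 km (ocean-basin tracks).
"""

from __future__ import annotations

import numpy as np

#: Authalic (equal-area) Earth radius, km.
EARTH_RADIUS_KM = 6371.0072


def _to_rad(*vals):
    return tuple(np.radians(np.asarray(v, dtype=float)) for v in vals)


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance between points, km (haversine formula)."""
    lam1, phi1, lam2, phi2 = _to_rad(lon1, lat1, lon2, lat2)
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing(lon1, lat1, lon2, lat2):
    """Initial compass bearing (radians in [0, 2*pi)) from point 1 to point 2."""
    lam1, phi1, lam2, phi2 = _to_rad(lon1, lat1, lon2, lat2)
    dlam = lam2 - lam1
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    return np.mod(np.arctan2(y, x), 2.0 * np.pi)


def destination(lon, lat, bearing_rad, distance_km):
    """Destination point reached from (lon, lat) on the given compass bearing.

    Returns (lon, lat) in degrees, longitude normalized to [-180, 180).
    """
    lam1, phi1 = _to_rad(lon, lat)
    theta = np.asarray(bearing_rad, dtype=float)
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    lon2 = np.degrees(lam2)
    lon2 = np.mod(lon2 + 180.0, 360.0) - 180.0
    return lon2, np.degrees(phi2)


def wrap_angle(angle_rad):
    """Wrap an angle (radians) to the interval (-pi, pi]."""
    a = np.mod(np.asarray(angle_rad, dtype=float), 2.0 * np.pi)
    out = np.where(a > np.pi, a - 2.0 * np.pi, a)
    # map exactly -pi to +pi so the interval is half-open on the left
    out = np.where(np.isclose(out, -np.pi), np.pi, out)
    if np.ndim(angle_rad) == 0:
        return float(out)
    return out


def turn_angle(bearing_in, bearing_out):
    """Signed turn between consecutive displacements, counterclockwise positive.

    A right (clockwise) turn of 90 degrees yields -pi/2.
    """
    return wrap_angle(-(np.asarray(bearing_out) - np.asarray(bearing_in)))
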