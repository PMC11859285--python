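"""Geodetic-to-planar conversion and horizontal-distance primitives.

A 400 m track comfortably fits a local East-North-Up (ENU) tangent plane on
the WGS-84 ellipsoid: over a <1 km baseline the planar approximation error is
sub-millimetre, so step lengths and cumulative distance can be computed with
plain Euclidean geometry in the local frame. The origin is the first GNSS
epoch; conversion goes geodetic -> ECEF -> ENU (and back, for simulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, ValidationError

# WGS-84 ellipsoid
WGS84_A = 6378137.0               # semi-major axis [m]
WGS84_F = 1.0 / 298.257223563     # flattening
WGS84_B = WGS84_A * (1.0 - WGS84_F)
WGS84_E2 = WGS84_F * (2.0 - WGS84_F)   # first eccentricity squared

MAX_SPAN_M = 10_000.0  # tangent-plane validity guard


@dataclass
class LocalTrack:
    """GNSS trajectory expressed in a local ENU frame.

    Arrays share one length; ``origin`` is the geodetic (lat, lon, h) of the
    first sample, which maps to (e, n, u) = (0, 0, 0).
    """

    t: np.ndarray          # seconds
    e: np.ndarray          # metres east
    n: np.ndarray          # metres north
    u: np.ndarray          # metres up (ellipsoidal height - origin height)
    status: np.ndarray     # per-sample "FIX"/"FLOAT"
    origin: tuple[float, float, float]
    nominal_rate: float = 100.0

    def __post_init__(self):
        lengths = {len(self.t), len(self.e), len(self.n), len(self.u), len(self.status)}
        if len(lengths) != 1:
            raise ValueError("LocalTrack arrays must share one length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("LocalTrack time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


def geodetic_to_ecef(lat_deg, lon_deg, h):
    """WGS-84 geodetic coordinates to Earth-centred Earth-fixed XYZ [m]."""
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    lon = np.radians(np.asarray(lon_deg, dtype=float))
    h = np.asarray(h, dtype=float)
    sin_lat, cos_lat = np.sin(lat), np.cos(lat)
    nrad = WGS84_A / np.sqrt(1.0 - WGS84_E2 * sin_lat**2)  # prime vertical radius
    x = (nrad + h) * cos_lat * np.cos(lon)
    y = (nrad + h) * cos_lat * np.sin(lon)
    z = (nrad * (1.0 - WGS84_E2) + h) * sin_lat
    return x, y, z


def ecef_to_geodetic(x, y, z):
    """ECEF XYZ to WGS-84 geodetic (lat_deg, lon_deg, h).

    Bowring's closed-form start followed by two Newton refinements; accurate
    to well below 1 mm for near-surface points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    lon = np.arctan2(y, x)
    p = np.hypot(x, y)
    # Bowring initial guess
    theta = np.arctan2(z * WGS84_A, p * WGS84_B)
    ep2 = (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    lat = np.arctan2(z + ep2 * WGS84_B * np.sin(theta) ** 3,
                     p - WGS84_E2 * WGS84_A * np.cos(theta) ** 3)
    for _ in range(3):
        sin_lat = np.sin(lat)
        nrad = WGS84_A / np.sqrt(1.0 - WGS84_E2 * sin_lat**2)
        h = p / np.cos(lat) - nrad
        lat = np.arctan2(z, p * (1.0 - WGS84_E2 * nrad / (nrad + h)))
    sin_lat = np.sin(lat)
    nrad = WGS84_A / np.sqrt(1.0 - WGS84_E2 * sin_lat**2)
    h = p / np.cos(lat) - nrad
    return np.degrees(lat), np.degrees(lon), h


def _enu_rotation(lat0_deg: float, lon0_deg: float) -> np.ndarray:
    """Rotation matrix taking ECEF deltas to local (e, n, u) at the origin."""
    lat0 = np.radians(lat0_deg)
    lon0 = np.radians(lon0_deg)
    sl, cl = np.sin(lat0), np.cos(lat0)
    so, co = np.sin(lon0), np.cos(lon0)
    return np.array([
        [-so, co, 0.0],
        [-sl * co, -sl * so, cl],
        [cl * co, cl * so, sl],
    ])


def to_local_enu(traj) -> LocalTrack:
    """Express a geodetic trajectory in the ENU tangent frame of its first epoch.

    ``u`` equals ellipsoidal height minus origin height (exactly, by
    construction of the ENU rotation at the origin only up to curvature; the
    height identity is enforced by using the geodetic heights directly).
    """
    lat = np.asarray([s.lat for s in traj.samples])
    lon = np.asarray([s.lon for s in traj.samples])
    h = np.asarray([s.h for s in traj.samples])
    t = np.asarray([s.t for s in traj.samples])
    status = np.asarray([s.status.name for s in traj.samples])
    lat0, lon0, h0 = float(lat[0]), float(lon[0]), float(h[0])

    x, y, z = geodetic_to_ecef(lat, lon, h)
    x0, y0, z0 = geodetic_to_ecef(lat0, lon0, h0)
    rot = _enu_rotation(lat0, lon0)
    d = np.vstack([x - x0, y - y0, z - z0])
    e, n, u = rot @ d
    # For heights the direct difference is exact and free of tangent-plane
    # curvature; over <10 km the two agree to <8 mm, but the contract is the
    # height difference.
    u = h - h0

    span = float(np.max(np.hypot(e, n))) if len(e) else 0.0
    if span > MAX_SPAN_M:
        raise ValidationError(
            f"trajectory span {span:.0f} m exceeds {MAX_SPAN_M:.0f} m; "
            "tangent-plane assumption violated"
        )
    return LocalTrack(t=t, e=e, n=n, u=u, status=status,
                      origin=(lat0, lon0, h0), nominal_rate=traj.nominal_rate)


def enu_to_geodetic(e, n, u, origin):
    """Invert the ENU mapping at ``origin`` = (lat0, lon0, h0).

    Used by the simulator to produce geodetic samples from a planar track.
    The vertical is treated as in :func:`to_local_enu`: the returned height is
    origin height + u, and (e, n) are laid on the tangent plane.
    """
    lat0, lon0, h0 = origin
    x0, y0, z0 = geodetic_to_ecef(lat0, lon0, h0)
    rot = _enu_rotation(lat0, lon0)
    e = np.asarray(e, dtype=float)
    n = np.asarray(n, dtype=float)
    u = np.asarray(u, dtype=float)
    dxyz = rot.T @ np.vstack([e, n, np.zeros_like(e)])
    lat, lon, _ = ecef_to_geodetic(x0 + dxyz[0], y0 + dxyz[1], z0 + dxyz[2])
    # Round-trip consistency with to_local_enu: height carries u directly.
    return lat, lon, h0 + u


def horizontal_displacement(track: LocalTrack, i: int, j: int) -> float:
    """Planar chord between samples i and j; the vertical is ignored."""
    return float(np.hypot(track.e[j] - track.e[i], track.n[j] - track.n[i]))


def cumulative_distance(e, n) -> np.ndarray:
    """Cumulative planar path length along a track; c[0] = 0, non-decreasing."""
    e = np.asarray(e, dtype=float)
    n = np.asarray(n, dtype=float)
    seg = np.hypot(np.diff(e), np.diff(n))
    return np.concatenate([[0.0], np.cumsum(seg)])


def time_at_distance(t, cum_dist, d: float) -> float:
    """Time at which the cumulative horizontal distance first reaches ``d``.

    Linear interpolation between the bracketing samples; exact at samples.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(cum_dist, dtype=float)
    if d < 0:
        raise ValueError("distance must be non-negative")
    if d > c[-1]:
        raise DataError(f"distance {d} m never reached (track ends at {c[-1]:.3f} m)")
    k = int(np.searchsorted(c, d, side="left"))
    if c[k] == d:
        return float(t[k])
    frac = (d - c[k - 1]) / (c[k] - c[k - 1])
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))
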