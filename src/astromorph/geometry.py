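"""Flat-mount retinal coordinates and eccentricity trends.

The flattened retina is treated as an azimuthal-equidistant projection of a
hemisphere: latitude is linear in the normalised planar distance from the
optic nerve head (ONH), with the ONH at -90 deg, the rim (far periphery) at
0 deg, and longitude oriented so that the dorsal direction is always
+90 deg (0 deg is temporal for left eyes and nasal for right eyes).  Right
eyes are harmonised into left-eye space by mirroring longitude about the
dorsal-ventral axis.  The hemisphere opening angle phi0 used by full elastic
flat-mount reconstructions is carried for provenance only; the simplified
projection does not use it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RetinalCoordinate",
    "TrendFit",
    "map_to_sphere",
    "sphere_to_planar",
    "harmonize_eye",
    "eccentricity_trend",
]

_HALF_PI = np.pi / 2.0


@dataclass(frozen=True)
class RetinalCoordinate:
    """Hemispherical position of a cell (latitude in [-pi/2, 0], radians)."""

    latitude: float
    longitude: float
    eye: str  # "left" | "right"
    planar_xy_um: tuple[float, float] | None = None

    def __post_init__(self):
        if not -_HALF_PI - 1e-12 <= self.latitude <= 1e-12:
            raise ValueError("latitude outside [-pi/2, 0]")
        if self.eye not in ("left", "right"):
            raise ValueError("eye must be 'left' or 'right'")


@dataclass(frozen=True)
class TrendFit:
    """Quadratic trend of a morphology value against latitude."""

    a: float
    b: float
    c: float
    curvature: str  # "negative" | "positive" | "flat"
    residual_sd: float


def map_to_sphere(
    planar_xy_um: tuple[float, float],
    onh_xy_um: tuple[float, float],
    rim_distance_um: float,
    dorsal_angle_deg: float = 90.0,
    eye: str = "left",
    phi0_deg: float = 22.0,
) -> RetinalCoordinate:
    """Map a flattened-retina position to (latitude, longitude).

    ``dorsal_angle_deg`` is the planar polar angle (CCW from +x) of the
    dorsal reference direction; longitude is rotated so that direction maps
    to +90 deg.  ``phi0_deg`` is recorded by callers for provenance but does
    not enter the simplified azimuthal-equidistant mapping.
    """
    del phi0_deg
    dx = planar_xy_um[0] - onh_xy_um[0]
    dy = planar_xy_um[1] - onh_xy_um[1]
    r = float(np.hypot(dx, dy))
    if r > rim_distance_um * (1 + 1e-9):
        raise ValueError("point beyond rim")
    lat = (min(r, rim_distance_um) / rim_distance_um - 1.0) * _HALF_PI
    theta = float(np.arctan2(dy, dx))
    lon = (theta - np.radians(dorsal_angle_deg) + _HALF_PI) % (2 * np.pi)
    return RetinalCoordinate(
        latitude=float(lat), longitude=float(lon), eye=eye, planar_xy_um=tuple(planar_xy_um)
    )


def sphere_to_planar(
    coord: RetinalCoordinate,
    onh_xy_um: tuple[float, float],
    rim_distance_um: float,
    dorsal_angle_deg: float = 90.0,
) -> tuple[float, float]:
    """Inverse of :func:`map_to_sphere` (same eye, same orientation)."""
    r = (coord.latitude / _HALF_PI + 1.0) * rim_distance_um
    theta = coord.longitude + np.radians(dorsal_angle_deg) - _HALF_PI
    return (
        float(onh_xy_um[0] + r * np.cos(theta)),
        float(onh_xy_um[1] + r * np.sin(theta)),
    )


def harmonize_eye(coord: RetinalCoordinate) -> RetinalCoordinate:
    """Translate a right-eye coordinate into left-eye space.

    Longitude is mirrored about the dorsal-ventral axis (λ -> π - λ mod 2π),
    which fixes dorsal (+90 deg) and maps right-eye nasal (0 deg) onto the
    left-eye nasal position (180 deg); latitude is unchanged.  Left-eye
    coordinates pass through untouched.
    """
    if coord.eye == "left":
        return coord
    lon = (np.pi - coord.longitude) % (2 * np.pi)
    return replace(coord, longitude=float(lon))


def eccentricity_trend(values, latitudes, flat_tol_factor: float = 1e-6) -> TrendFit:
    """Ordinary least-squares quadratic fit of a value against latitude.

    Curvature is the sign of the quadratic coefficient; |a| below
    ``flat_tol_factor`` times the value scale is reported "flat" so that
    noise cannot masquerade as curvature.
    """
    v = np.asarray(values, float)
    lat = np.asarray(latitudes, float)
    if v.shape != lat.shape or v.ndim != 1:
        raise ValueError("values and latitudes must be equal-length 1D arrays")
    if len(np.unique(lat)) < 3:
        raise ValueError("rank-deficient design: need >=3 distinct latitudes")
    a, b, c = np.polyfit(lat, v, 2)
    resid = v - (a * lat**2 + b * lat + c)
    dof = max(len(v) - 3, 1)
    residual_sd = float(np.sqrt((resid**2).sum() / dof))
    scale = float(np.max(np.abs(v))) or 1.0
    if abs(a) < flat_tol_factor * scale:
        curvature = "flat"
    else:
        curvature = "negative" if a < 0 else "positive"
    return TrendFit(float(a), float(b), float(c), curvature, residual_sd)
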