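"""Spherical coordinates and angular separations of cardiac axes.

All angles are in degrees, all vectors in the DICOM LPS frame (+x left,
+y posterior, +z superior). The two spherical coordinates are

theta
    Frontal-plane (x-z plane) angle, ``atan2(-z, x)``: 0 deg points left,
    positive rotates toward inferior (the clinical frontal-axis convention,
    anticlockwise negative), range (-180, 180].
phi
    Polar angle from the anterior-posterior axis, ``arccos(y)``: 0 deg is
    posterior, 180 deg anterior, range [0, 180].

The full 3D separation between an anatomical and an electrical axis,
``angle_3d``, is the arc cosine of their dot product and is deliberately NOT
folded to an acute angle: apex->base anatomical directions sit roughly
opposite the depolarisation direction, so population means are obtuse.
Planar deltas, by contrast, use minimal signed wrapping to avoid artificial
extremes at the +/-180 boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from cardaxes.errors import DegenerateGeometryError, UsageError

PLANES = ("frontal", "transverse", "sagittal")

#: Alternative phi convention (see package config): elevation from the
#: transverse plane instead of polar angle from +y. Kept selectable so the
#: convention can be swapped without touching callers.
PHI_CONVENTIONS = ("polar_from_posterior", "elevation_from_transverse")


@dataclass(frozen=True)
class SphericalAngles:
    """(theta, phi) in degrees; ``degenerate`` marks the phi = 0/180 pole
    where theta is undefined and returned as 0 by convention."""

    theta: float
    phi: float
    degenerate: bool = False


def _check_unit(v: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise UsageError("expected a 3-vector")
    if abs(np.linalg.norm(v) - 1.0) > tol:
        raise UsageError(f"expected a unit vector, got norm {np.linalg.norm(v)}")
    return v


def to_spherical(
    direction: np.ndarray, phi_convention: str = "polar_from_posterior"
) -> SphericalAngles:
    """Convert an LPS unit vector to (theta, phi) degrees."""
    v = _check_unit(direction)
    x, y, z = v
    if phi_convention == "polar_from_posterior":
        phi = np.degrees(np.arccos(np.clip(y, -1.0, 1.0)))
    elif phi_convention == "elevation_from_transverse":
        phi = 90.0 - np.degrees(np.arccos(np.clip(y, -1.0, 1.0)))
    else:
        raise UsageError(f"unknown phi convention {phi_convention!r}")
    in_plane = np.hypot(x, z)
    if in_plane < 1e-9:
        return SphericalAngles(theta=0.0, phi=float(phi), degenerate=True)
    theta = np.degrees(np.arctan2(-z, x))
    if theta <= -180.0:
        theta += 360.0
    return SphericalAngles(theta=float(theta), phi=float(phi))


def from_spherical(theta: float, phi: float) -> np.ndarray:
    """Inverse of :func:`to_spherical` (polar-from-posterior convention)."""
    th, ph = np.radians(theta), np.radians(phi)
    y = np.cos(ph)
    r = np.sin(ph)
    return np.array([r * np.cos(th), y, -r * np.sin(th)])


def angle_3d(a: np.ndarray, e: np.ndarray) -> float:
    """3D angular separation in degrees: arccos(a . e), clamped, in [0, 180]."""
    a = _check_unit(a)
    e = _check_unit(e)
    return float(np.degrees(np.arccos(np.clip(a @ e, -1.0, 1.0))))


def planar_angle(direction: np.ndarray, plane: str) -> float:
    """In-plane angle of a direction's projection, signed degrees (-180, 180].

    frontal = atan2(-z, x); transverse = atan2(y, x); sagittal = atan2(-z, y).
    """
    v = _check_unit(direction)
    x, y, z = v
    if plane == "frontal":
        u, w = x, -z
    elif plane == "transverse":
        u, w = x, y
    elif plane == "sagittal":
        u, w = y, -z
    else:
        raise UsageError(f"unknown plane {plane!r}; expected one of {PLANES}")
    if np.hypot(u, w) <= 1e-6:
        raise DegenerateGeometryError(
            f"direction is normal to the {plane} plane; in-plane angle undefined"
        )
    ang = float(np.degrees(np.arctan2(w, u)))
    return ang + 360.0 if ang <= -180.0 else ang


def signed_delta(angle_a: float, angle_e: float) -> float:
    """Minimal signed difference angle_a - angle_e wrapped into (-180, 180]."""
    d = (float(angle_a) - float(angle_e)) % 360.0
    if d > 180.0:
        d -= 360.0
    elif d <= -180.0:
        d += 360.0
    return d


def spatial_consistency(deltas: Iterable[float]) -> dict[str, float]:
    """Spread of the 3D angular separations across a population.

    Returns the sample SD of the angles (degrees) and of their cosines
    (dimensionless). Lower SD = higher spatial consistency, i.e. a more
    reproducible anatomical-electrical relationship.
    """
    arr = np.asarray(list(deltas), dtype=float)
    if len(arr) < 2:
        raise UsageError("need at least 2 angular separations")
    return {
        "sd_angle": float(np.std(arr, ddof=1)),
        "sd_cosine": float(np.std(np.cos(np.radians(arr)), ddof=1)),
    }
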