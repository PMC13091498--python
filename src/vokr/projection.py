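"""Dual-camera projection of 3D eye orientation.

The eye is modeled as a triaxial ellipsoid with semi-axes ``a`` (long,
naso-temporal), ``b`` (dorso-ventral) and ``c`` (medio-lateral), a > b > c.
Body coordinates: x = rostro-caudal (body axis), y = medio-lateral,
z = dorso-ventral.  A horizontal eye rotation is a yaw ``h`` about z; a
vertical one is a roll ``v`` about the eye's own rostro-caudal axis.
Rotations compose yaw first, then roll about the already-yawed axis
(``R = R_z(h) R_x(v)``).  With this composition the top camera reads the
true yaw exactly, while the front camera's apparent angle is corrupted
when a large yaw accompanies the roll -- the artifact seen in real
dual-camera recordings.

Each camera sees the orthographic shadow of the ellipsoid:

* top camera looks along z and sees the (x, y) plane,
* front camera looks along x and sees the (y, z) plane.

For an ellipsoid ``{u : u^T M u = 1}`` the shadow onto a coordinate plane
is the ellipse whose 2x2 matrix is the Schur complement of the viewing
coordinate in M.  The apparent angle is the angle of the shadow's major
axis: against the body axis (x) in the top view and against the
dorso-ventral axis (z) in the front view, with signs chosen so that a
yaw of +h reads +h on the top camera and a roll of +v reads +v on the
front camera at rest.

This reproduces the projection artifact of dual-camera oculography: once
both rotations are large the front-view shadow becomes more circular and
its major-axis angle no longer equals the true vertical rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EyeGeometry",
    "ProjectedEllipse",
    "DegenerateGeometryError",
    "project_eye_orientation",
    "render_eye_frame",
]


class DegenerateGeometryError(ValueError):
    """Raised when the ellipsoid axes do not satisfy a > b > c > 0."""


@dataclass(frozen=True)
class EyeGeometry:
    """Ellipsoid semi-axes (px) and per-camera image centers (col, row)."""

    a: float = 50.0
    b: float = 40.0
    c: float = 32.0
    top_center: tuple = (128.0, 128.0)
    front_center: tuple = (128.0, 128.0)

    def __post_init__(self) -> None:
        if not (self.a > self.b > self.c > 0):
            raise DegenerateGeometryError(
                f"require a > b > c > 0, got ({self.a}, {self.b}, {self.c})")


@dataclass
class ProjectedEllipse:
    """Apparent ellipse of one camera: angle (deg) and full axis lengths (px)."""

    angle: np.ndarray | float
    major_len: np.ndarray | float
    minor_len: np.ndarray | float


def _wrap_half(angle_deg):
    """Wrap an axial angle to [-90, 90)."""
    return (np.asarray(angle_deg) + 90.0) % 180.0 - 90.0


def _shadow(E00, E01, E11):
    """Semi-axes and major-axis angle (from the first plane coordinate)
    of the ellipse p^T E p = 1 for symmetric 2x2 E, vectorized."""
    mean = 0.5 * (E00 + E11)
    diff = 0.5 * (E00 - E11)
    rad = np.sqrt(diff * diff + E01 * E01)
    lam_min = mean - rad  # major axis: semi-axis = 1/sqrt(lambda)
    lam_max = mean + rad
    major = 1.0 / np.sqrt(lam_min)
    minor = 1.0 / np.sqrt(lam_max)
    theta = 0.5 * np.degrees(np.arctan2(-2.0 * E01, E11 - E00))
    return major, minor, theta


def _ellipsoid_matrix(h_deg, v_deg, geometry: EyeGeometry):
    """3x3 shape matrices M = R D R^T, vectorized over orientation arrays."""
    h = np.radians(np.asarray(h_deg, dtype=float))
    v = np.radians(np.asarray(v_deg, dtype=float))
    h, v = np.broadcast_arrays(h, v)
    ch, sh = np.cos(h), np.sin(h)
    cv, sv = np.cos(v), np.sin(v)
    # R = R_z(h) @ R_x(v); rows of R expressed with broadcast scalars.
    zeros = np.zeros_like(ch)
    R = np.stack([
        np.stack([ch, -sh * cv, sh * sv], axis=-1),
        np.stack([sh, ch * cv, -ch * sv], axis=-1),
        np.stack([zeros, sv, cv], axis=-1),
    ], axis=-2)
    d = np.array([1.0 / geometry.a**2, 1.0 / geometry.c**2,
                  1.0 / geometry.b**2])
    M = np.einsum("...ik,k,...jk->...ij", R, d, R)
    return M


def project_eye_orientation(h_deg, v_deg, geometry: EyeGeometry | None = None):
    """Apparent per-camera ellipse for true yaw ``h`` and roll ``v`` (deg).

    Accepts scalars or arrays (broadcast together); |h| and |v| must be
    below 90 deg.  Returns ``{"top": ProjectedEllipse, "front":
    ProjectedEllipse}``; angles are wrapped to [-90, 90).
    """
    geometry = geometry or EyeGeometry()
    h_arr = np.asarray(h_deg, dtype=float)
    v_arr = np.asarray(v_deg, dtype=float)
    if np.any(np.abs(h_arr) >= 90) or np.any(np.abs(v_arr) >= 90):
        raise ValueError("|h| and |v| must be < 90 deg")
    scalar = h_arr.ndim == 0 and v_arr.ndim == 0
    M = _ellipsoid_matrix(h_arr, v_arr, geometry)

    # Top view: drop z (index 2); plane coords (x, y).
    E00 = M[..., 0, 0] - M[..., 0, 2] ** 2 / M[..., 2, 2]
    E01 = M[..., 0, 1] - M[..., 0, 2] * M[..., 1, 2] / M[..., 2, 2]
    E11 = M[..., 1, 1] - M[..., 1, 2] ** 2 / M[..., 2, 2]
    maj_t, min_t, theta_t = _shadow(E00, E01, E11)
    top_angle = _wrap_half(theta_t)

    # Front view: drop x (index 0); plane coords (y, z), angle from z.
    F00 = M[..., 1, 1] - M[..., 0, 1] ** 2 / M[..., 0, 0]
    F01 = M[..., 1, 2] - M[..., 0, 1] * M[..., 0, 2] / M[..., 0, 0]
    F11 = M[..., 2, 2] - M[..., 0, 2] ** 2 / M[..., 0, 0]
    maj_f, min_f, theta_f = _shadow(F00, F01, F11)
    # theta_f is measured from the y axis; re-reference to the z axis so a
    # positive roll reads positive.
    front_angle = _wrap_half(theta_f - 90.0)

    def out(angle, major, minor):
        if scalar:
            return ProjectedEllipse(float(angle), float(2 * major),
                                    float(2 * minor))
        return ProjectedEllipse(angle, 2 * major, 2 * minor)

    return {"top": out(top_angle, maj_t, min_t),
            "front": out(front_angle, maj_f, min_f)}


def render_eye_frame(h_deg: float, v_deg: float,
                     geometry: EyeGeometry | None = None,
                     shape: tuple = (256, 256),
                     camera: str = "top") -> np.ndarray:
    """Binary image of the projected eye for one camera.

    Pixels inside the shadow ellipse are set to True.  Image axes: columns
    increase along the first plane coordinate (x for top, y for front),
    rows increase *downward* along the negative second coordinate, so the
    rendering matches the moment-based tracker's angle convention.
    """
    geometry = geometry or EyeGeometry()
    M = _ellipsoid_matrix(h_deg, v_deg, geometry)
    if camera == "top":
        i, j, k = 0, 1, 2
        cx, cy = geometry.top_center
    elif camera == "front":
        i, j, k = 1, 2, 0
        cx, cy = geometry.front_center
    else:
        raise ValueError("camera must be 'top' or 'front'")
    E00 = M[i, i] - M[i, k] ** 2 / M[k, k]
    E01 = M[i, j] - M[i, k] * M[j, k] / M[k, k]
    E11 = M[j, j] - M[j, k] ** 2 / M[k, k]
    E = np.array([[E00, E01], [E01, E11]])
    # Bounding half-widths: extent along plane axis e is sqrt(e^T E^-1 e).
    Einv = np.linalg.inv(E)
    wx, wy = np.sqrt(np.diag(Einv))
    rows, cols = shape
    if (cx - wx < 0 or cx + wx > cols - 1 or cy - wy < 0
            or cy + wy > rows - 1):
        raise ValueError("projected ellipse does not fit in the frame")
    col = np.arange(cols)[None, :] - cx
    row = np.arange(rows)[:, None] - cy
    u1 = col + 0.0 * row
    u2 = -row + 0.0 * col  # second plane coordinate points up
    q = E00 * u1**2 + 2 * E01 * u1 * u2 + E11 * u2**2
    return q <= 1.0
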