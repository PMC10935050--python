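"""Small quaternion helpers on top of scipy's Rotation.

Public convention everywhere in this package: Hamilton quaternions, scalar-first
(w, x, y, z), world-from-sensor.  scipy stores scalar-last, so these wrappers do
the reordering in one place.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "quat_to_rotation",
    "rotation_to_quat",
    "enforce_sign_continuity",
    "quat_multiply",
    "rotvec_quat",
    "align_to_z",
]


def quat_to_rotation(q_wxyz: np.ndarray) -> Rotation:
    """Rotation object from scalar-first quaternion array (…, 4)."""
    q = np.asarray(q_wxyz, dtype=float)
    return Rotation.from_quat(np.roll(q, -1, axis=-1))


def rotation_to_quat(rot: Rotation) -> np.ndarray:
    """Scalar-first quaternion array from a Rotation (sign not continuity-fixed)."""
    return np.roll(np.atleast_2d(rot.as_quat()), 1, axis=-1)


def enforce_sign_continuity(q: np.ndarray) -> np.ndarray:
    """Flip quaternion signs in place so that q[k]·q[k+1] >= 0 along the series."""
    dots = np.einsum("ij,ij->i", q[:-1], q[1:])
    flip = np.cumprod(np.where(dots < 0.0, -1.0, 1.0))
    q[1:] *= flip[:, None]
    return q


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a*b for single scalar-first quaternions."""
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def rotvec_quat(rotvec: np.ndarray) -> np.ndarray:
    """Scalar-first unit quaternion of a rotation vector (axis * angle)."""
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-300:
        return np.array([1.0, 0.0, 0.0, 0.0])
    half = 0.5 * angle
    axis = rotvec / angle
    s = np.sin(half)
    return np.array([np.cos(half), s * axis[0], s * axis[1], s * axis[2]])


def align_to_z(vec: np.ndarray) -> Rotation:
    """Minimal rotation taking the direction of ``vec`` onto the world +z axis.

    The rotation axis is horizontal (vec x z), so heading (yaw) is untouched —
    this is the tilt-only correction used during stance.
    """
    v = np.asarray(vec, dtype=float)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        return Rotation.identity()
    v = v / norm
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    c = float(np.dot(v, z))
    angle = np.arctan2(s, c)
    if s < 1e-15:
        if c > 0.0:
            return Rotation.identity()
        # antiparallel: rotate about x by pi (degenerate, heading arbitrary)
        return Rotation.from_rotvec([np.pi, 0.0, 0.0])
    return Rotation.from_rotvec(axis / s * angle)
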