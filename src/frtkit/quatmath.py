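"""Quaternion algebra for attitude representation.

Conventions used throughout the package:

* Quaternions are **scalar-first** ``(w, x, y, z)`` arrays and represent the
  rotation of the sensor (body) frame relative to the local ENU Earth frame
  (x east, y geomagnetic north, z up).
* Hamilton (right-handed) multiplication.  A unit quaternion ``q`` maps a
  sensor-frame vector ``v`` into the Earth frame via the sandwich product
  ``q ⊗ (0, v) ⊗ q*``; the conjugate sandwich maps Earth to sensor.
* ``q`` and ``-q`` encode the same rotation.

Euler angles follow the aerospace Tait-Bryan convention: intrinsic Z-Y-X,
i.e. yaw ψ about z, then pitch θ about the new y, then roll ϕ about the new
x, with ϕ, ψ ∈ [-180°, 180°] and θ ∈ [-90°, 90°].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "identity",
    "normalize",
    "conjugate",
    "multiply",
    "rotate_vector",
    "rotation_matrix",
    "to_euler",
    "from_euler",
    "from_axis_angle",
    "angular_distance",
]

_UNIT_TOL = 1e-6


def identity() -> np.ndarray:
    """The no-rotation quaternion ``(1, 0, 0, 0)``."""
    return np.array([1.0, 0.0, 0.0, 0.0])


def normalize(q: np.ndarray) -> np.ndarray:
    """Return ``q / ||q||``.

    Raises
    ------
    ValueError
        If ``q`` has (near-)zero norm.
    """
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize a zero-norm quaternion")
    return q / n


def conjugate(q: np.ndarray) -> np.ndarray:
    """Quaternion conjugate ``(w, -x, -y, -z)`` (inverse for unit q)."""
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a ⊗ b`` of scalar-first quaternions.

    Supports broadcasting over leading axes; the last axis must have
    length 4.  ``||a ⊗ b|| = ||a||·||b||``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def _require_unit(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(n - 1.0) > _UNIT_TOL):
        raise ValueError("quaternion must be unit-norm")
    return q


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by unit quaternion(s) ``q`` (sensor → Earth).

    Computes the vector part of ``q ⊗ (0, v) ⊗ q*``.  Norm-preserving.
    Broadcasts over leading axes (e.g. an (n, 4) quaternion track against an
    (n, 3) sample track).
    """
    q = _require_unit(q)
    v = np.asarray(v, dtype=float)
    pure = np.concatenate([np.zeros(v.shape[:-1] + (1,)), v], axis=-1)
    out = multiply(multiply(q, pure), conjugate(q))
    return out[..., 1:]


def rotation_matrix(q: np.ndarray) -> np.ndarray:
    """3×3 direction-cosine matrix equivalent of unit quaternion ``q``.

    ``rotation_matrix(q) @ v == rotate_vector(q, v)``.
    """
    w, x, y, z = _require_unit(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def to_euler(q: np.ndarray, degrees: bool = True) -> np.ndarray:
    """Convert unit quaternion(s) to (roll ϕ, pitch θ, yaw ψ).

    Intrinsic Z-Y-X Tait-Bryan decomposition.  Outputs satisfy
    ϕ, ψ ∈ [-180°, 180°] and θ ∈ [-90°, 90°].  At gimbal lock
    (|θ| = 90°) the roll angle is set to zero and yaw carries the full
    remaining rotation.
    """
    q = _require_unit(np.asarray(q, dtype=float))
    w, x, y, z = np.moveaxis(q, -1, 0)
    sin_pitch = np.clip(2.0 * (w * y - z * x), -1.0, 1.0)
    pitch = np.arcsin(sin_pitch)
    gimbal = np.abs(sin_pitch) > 1.0 - 1e-12
    roll = np.where(
        gimbal, 0.0, np.arctan2(2.0 * (w * x + y * z), 1.0 - 2.0 * (x * x + y * y))
    )
    yaw = np.where(
        gimbal,
        # at lock only the ψ∓ϕ combination is observable; report it all as yaw
        2.0 * np.arctan2(z, w),
        np.arctan2(2.0 * (w * z + x * y), 1.0 - 2.0 * (y * y + z * z)),
    )
    ang = np.stack([roll, pitch, yaw], axis=-1)
    return np.degrees(ang) if degrees else ang


def from_euler(roll: float, pitch: float, yaw: float, degrees: bool = True) -> np.ndarray:
    """Quaternion from (roll, pitch, yaw), intrinsic Z-Y-X order."""
    if degrees:
        roll, pitch, yaw = np.radians([roll, pitch, yaw])
    cr, sr = np.cos(roll / 2), np.sin(roll / 2)
    cp, sp = np.cos(pitch / 2), np.sin(pitch / 2)
    cy, sy = np.cos(yaw / 2), np.sin(yaw / 2)
    return np.array(
        [
            cy * cp * cr + sy * sp * sr,
            cy * cp * sr - sy * sp * cr,
            cy * sp * cr + sy * cp * sr,
            sy * cp * cr - cy * sp * sr,
        ]
    )


def from_axis_angle(axis: np.ndarray, angle_rad: float | np.ndarray) -> np.ndarray:
    """Quaternion for a rotation of ``angle_rad`` about unit ``axis``.

    ``angle_rad`` may be an array; the result then has one quaternion per
    angle (shape ``angle.shape + (4,)``).
    """
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("rotation axis must be nonzero")
    axis = axis / n
    angle = np.asarray(angle_rad, dtype=float)
    half = angle / 2.0
    return np.concatenate(
        [np.cos(half)[..., None], np.sin(half)[..., None] * axis], axis=-1
    )


def angular_distance(a: np.ndarray, b: np.ndarray, degrees: bool = True) -> np.ndarray:
    """Geodesic angle between two unit quaternions (sign-invariant)."""
    a = _require_unit(a)
    b = _require_unit(b)
    dot = np.clip(np.abs(np.sum(a * b, axis=-1)), 0.0, 1.0)
    ang = 2.0 * np.arccos(dot)
    return np.degrees(ang) if degrees else ang
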