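"""Earth-frame linear acceleration, double integration, and reach distance.

Once the orientation track is known, the accelerometer samples are rotated
into the ENU Earth frame and the constant 9.81 m·s⁻² gravity vector is
subtracted, leaving the linear acceleration of the device.  Velocity and
position follow by trapezoidal integration; a zero-phase high-pass
Butterworth filter (order 5, cutoff 0.01 Hz by default) is applied after
each integration stage to bound the drift that double integration of noisy
accelerometry inevitably accumulates.

The reach distance of a lean-and-return movement is the extent of the
position track along its principal horizontal direction: positions inside
the analysis window are projected onto the XOY (floor) plane, the first
principal axis of the centred point cloud is extracted, and the distance is
the spread (max − min) of the scalar projections onto that axis, reported
in centimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from . import quatmath as qm
from .preprocess import DRIFT_FILTER, FilterSpec, MovementWindow, apply_filter

__all__ = [
    "PoseSeries",
    "ReachResult",
    "earth_linear_accel",
    "integrate_position",
    "reach_distance",
]

GRAVITY = 9.81  # m·s⁻², Earth-frame +z


@dataclass
class PoseSeries:
    """Aligned orientation/kinematics tracks in the ENU Earth frame."""

    t: np.ndarray  # seconds
    accel_E: np.ndarray  # (n, 3) m·s⁻²
    velocity_E: np.ndarray  # (n, 3) m·s⁻¹
    position_E: np.ndarray  # (n, 3) m
    orientation: np.ndarray | None = None  # (n, 4) unit quaternions

    def __post_init__(self) -> None:
        n = len(self.t)
        for arr in (self.accel_E, self.velocity_E, self.position_E):
            if len(arr) != n:
                raise ValueError("PoseSeries tracks must share one length")


@dataclass(frozen=True)
class ReachResult:
    """Reach distance of one movement window."""

    distance_cm: float
    direction: np.ndarray  # unit 2-vector in the XOY plane
    window: MovementWindow


def earth_linear_accel(q: np.ndarray, a_S: np.ndarray) -> np.ndarray:
    """Linear acceleration in the Earth frame.

    ``a^E = q ⊗ a^S ⊗ q* − (0, 0, 9.81)`` per sample: the sensor-frame
    specific force is rotated into ENU and the gravity reaction removed.
    """
    q = np.asarray(q, dtype=float)
    a_S = np.asarray(a_S, dtype=float)
    if q.shape[:-1] != a_S.shape[:-1]:
        raise ValueError("quaternion and acceleration tracks differ in length")
    rotated = qm.rotate_vector(q, a_S)
    rotated[..., 2] -= GRAVITY
    return rotated


def integrate_position(
    accel_E: np.ndarray,
    rate: float,
    drift_filter: FilterSpec | None = DRIFT_FILTER,
    t0: float = 0.0,
    orientation: np.ndarray | None = None,
) -> PoseSeries:
    """Double-integrate Earth-frame acceleration to position.

    Cumulative trapezoidal integration from zero initial velocity and
    position; after each integration stage the track is high-pass filtered
    (zero-phase) with ``drift_filter`` to suppress low-frequency drift.
    Pass ``drift_filter=None`` to bypass filtering (analytic test paths).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    accel_E = np.atleast_2d(np.asarray(accel_E, dtype=float))
    n = accel_E.shape[0]
    t = t0 + np.arange(n) / rate
    vel = cumulative_trapezoid(accel_E, dx=1.0 / rate, axis=0, initial=0.0)
    if drift_filter is not None:
        vel = apply_filter(vel, drift_filter, rate)
    pos = cumulative_trapezoid(vel, dx=1.0 / rate, axis=0, initial=0.0)
    if drift_filter is not None:
        pos = apply_filter(pos, drift_filter, rate)
    return PoseSeries(t=t, accel_E=accel_E, velocity_E=vel, position_E=pos, orientation=orientation)


def principal_direction(xy: np.ndarray) -> np.ndarray:
    """First principal axis of a centred 2-D point cloud.

    Eigen-decomposition of the 2×2 covariance; for near-isotropic clouds the
    axis with the larger projected range wins, and the returned unit vector
    is oriented to have a non-negative east (x) component.
    """
    xy = np.asarray(xy, dtype=float)
    centred = xy - xy.mean(axis=0)
    cov = centred.T @ centred / max(len(xy) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    # eigh sorts ascending; candidate axes in descending eigenvalue order
    cands = [evecs[:, 1], evecs[:, 0]]
    if evals[1] - evals[0] <= 1e-12 * max(evals[1], 1e-30):
        ranges = [np.ptp(centred @ c) for c in cands]
        axis = cands[int(np.argmax(ranges))]
    else:
        axis = cands[0]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    return axis


def reach_distance(pose: PoseSeries, window: MovementWindow) -> ReachResult:
    """Reach distance of the movement inside ``window``.

    Positions are restricted to the window, projected onto the XOY plane,
    and the distance between the extreme points along the principal
    direction of the movement is reported in centimetres.
    """
    mask = (pose.t >= window.start - 1e-9) & (pose.t <= window.end + 1e-9)
    if np.count_nonzero(mask) < 2:
        raise ValueError("movement window contains fewer than 2 samples")
    xy = pose.position_E[mask, :2]
    axis = principal_direction(xy)
    proj = (xy - xy.mean(axis=0)) @ axis
    return ReachResult(distance_cm=float(np.ptp(proj) * 100.0), direction=axis, window=window)
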