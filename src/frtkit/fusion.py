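"""Orientation estimation: gyro propagation and gradient-descent MARG fusion.

The estimator follows the gradient-descent sensor-fusion scheme of Madgwick:
the gyroscope's quaternion derivative is integrated for short-term accuracy,
and a single normalized gradient step of an orientation objective — built
from the accelerometer's gravity reference and, optionally, the
magnetometer's Earth-field reference — corrects the long-term drift at every
sample.

Reference directions (Earth frame, ENU, z up):

* gravity  ``ĝ^E = (0, 0, 0, 1)`` — defines the vertical;
* magnetic ``b̂^E = (0, b_h, 0, b_v)`` — the measured field re-projected so
  its horizontal component lies on a single horizontal axis, which makes the
  filter immune to the (unknown) local declination and to slowly varying
  soft-iron bias.  Because the horizontal slot is the Earth *x* axis while
  geomagnetic north is the ENU *y* axis, the estimated yaw carries a fixed
  90° offset relative to a true-north reference; see
  :func:`frtkit.frt.benchmark_orientation`.

One gradient iteration per time sample is used, so the convergence rate is
bounded by the fusion gain ``beta`` (radians per second, roughly).  Because a
small ``beta`` makes the initial convergence from an arbitrary starting
quaternion slow, an optional accelerated-initialization schedule applies a
larger gain ``init_gain`` during the first ``init_time_s`` seconds — standard
practice for this filter family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import quatmath as qm

__all__ = [
    "AhrsConfig",
    "gyro_propagate",
    "gyro_propagate_omega",
    "objective",
    "objective_jacobian",
    "magnetic_reference",
    "madgwick_update",
    "run_ahrs",
]


@dataclass
class AhrsConfig:
    """Fusion parameters.

    Parameters
    ----------
    sample_period:
        Δt between samples, seconds.
    beta:
        Fusion gain weighting the normalized gradient step against the
        gyroscope propagation (rad·s⁻¹ of correction authority).  ``beta=0``
        disables all correction: the filter reduces exactly to gyroscope
        integration.
    mu:
        Step-size scale of a single gradient-descent iteration; kept at 1
        because the gradient is normalized and ``beta`` already sets the
        authority.  Exposed for experimentation.
    use_magnetometer:
        Include the Earth-field objective (yaw observability).
    initial_q:
        Starting orientation; defaults to identity.
    init_gain, init_time_s:
        Accelerated initialization: gain applied during the first
        ``init_time_s`` seconds.  ``init_gain=None`` disables the schedule.
    motion_gate_rad_s:
        Dynamic-motion gate: the accelerometer/magnetometer correction is
        suspended while the angular rate magnitude (within
        ``motion_gate_dilate_s`` of the sample, batch processing being
        offline) exceeds this threshold.  During a reach the accelerometer
        measures gravity *plus* the motion acceleration, so correcting
        against it would tilt the estimate to absorb exactly the signal the
        distance integration needs; gating leaves those samples to the
        gyroscope.  ``None`` disables the gate (plain filter behaviour).
    motion_gate_dilate_s:
        Half-width of the dilation of the gate mask, seconds.  Movement
        acceleration leads the angular rate at the onset of a lean, so the
        gate must open slightly before the rate threshold trips.
    """

    sample_period: float = 0.01
    beta: float = 0.1
    mu: float = 1.0
    use_magnetometer: bool = True
    initial_q: np.ndarray = field(default_factory=qm.identity)
    init_gain: float | None = 2.5
    init_time_s: float = 1.0
    motion_gate_rad_s: float | None = 0.05
    motion_gate_dilate_s: float = 0.5

    def __post_init__(self) -> None:
        if self.sample_period <= 0:
            raise ValueError("sample_period must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.mu <= 0:
            raise ValueError("mu must be positive")


GRAVITY_REF = np.array([0.0, 0.0, 0.0, 1.0])  # pure quaternion, z up


def gyro_propagate(q_prev: np.ndarray, omega: np.ndarray, dt: float) -> np.ndarray:
    """One step of gyroscope quaternion integration.

    ``q̇ = ½ q_prev ⊗ (0, ω)``; returns ``normalize(q_prev + q̇·dt)``.

    Parameters
    ----------
    q_prev: unit quaternion at the previous sample.
    omega: angular rate in the sensor frame, rad·s⁻¹.
    dt: sampling period, seconds (> 0).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    q_prev = np.asarray(q_prev, dtype=float)
    omega = np.asarray(omega, dtype=float)
    qdot = 0.5 * qm.multiply(q_prev, np.concatenate([[0.0], omega]))
    return qm.normalize(q_prev + qdot * dt)


def gyro_propagate_omega(q_prev: np.ndarray, omega: np.ndarray, dt: float) -> np.ndarray:
    """Gyro integration in the skew-symmetric rate-matrix form.

    Builds the 4×4 matrix Ω(ω) acting on scalar-first quaternions and
    returns ``normalize(q_prev + ½·Ω·q_prev·dt)`` — algebraically identical
    to :func:`gyro_propagate`; retained as an internal cross-check of the
    two standard formulations.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    wx, wy, wz = np.asarray(omega, dtype=float)
    Omega = np.array(
        [
            [0.0, -wx, -wy, -wz],
            [wx, 0.0, wz, -wy],
            [wy, -wz, 0.0, wx],
            [wz, wy, -wx, 0.0],
        ]
    )
    q_prev = np.asarray(q_prev, dtype=float)
    return qm.normalize(q_prev + 0.5 * (Omega @ q_prev) * dt)


def objective(q: np.ndarray, d: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Orientation objective ``f = vec(q* ⊗ d ⊗ q) − s``.

    ``d`` is a reference direction in the Earth frame and ``s`` the
    normalized measurement of it in the sensor frame, both passed as pure
    quaternions ``(0, x, y, z)``.  ``f = 0`` iff ``q`` rotates the reference
    onto the measurement.
    """
    s = np.asarray(s, dtype=float)
    if np.linalg.norm(s[1:]) < 1e-12:
        raise ValueError("measurement s has zero norm")
    sandwich = qm.multiply(qm.multiply(qm.conjugate(q), d), q)
    return sandwich[1:] - s[1:]


def objective_jacobian(q: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Analytic 3×4 Jacobian ∂f/∂q of :func:`objective` w.r.t. (w, x, y, z).

    Derived by differentiating the rotated reference ``R(q)ᵀ d`` entrywise;
    ``q`` is treated as a free ℝ⁴ vector, as usual for the single-iteration
    gradient step.
    """
    w, x, y, z = np.asarray(q, dtype=float)
    d1, d2, d3 = np.asarray(d, dtype=float)[1:]
    return 2.0 * np.array(
        [
            [
                z * d2 - y * d3,
                y * d2 + z * d3,
                -2 * y * d1 + x * d2 - w * d3,
                -2 * z * d1 + w * d2 + x * d3,
            ],
            [
                -z * d1 + x * d3,
                y * d1 - 2 * x * d2 + w * d3,
                x * d1 + z * d3,
                -w * d1 - 2 * z * d2 + y * d3,
            ],
            [
                y * d1 - x * d2,
                z * d1 - w * d2 - 2 * x * d3,
                w * d1 + z * d2 - 2 * y * d3,
                x * d1 + y * d2,
            ],
        ]
    )


def magnetic_reference(q_prev: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Earth-field reference ``b̂ = (0, √(hx²+hy²), 0, hz)`` from a raw field.

    The measured field is rotated into the Earth frame with the previous
    orientation estimate, ``h = q_prev ⊗ m̂ ⊗ q_prev*``, and its horizontal
    magnitude is collapsed onto one horizontal axis, discarding declination
    and first-order soft-iron error.  Returned as a unit pure quaternion.
    """
    m = np.asarray(m, dtype=float)
    n = np.linalg.norm(m)
    if n < 1e-12:
        raise ValueError("magnetometer measurement has zero norm")
    h = qm.rotate_vector(q_prev, m / n)
    b = np.array([0.0, np.hypot(h[0], h[1]), 0.0, h[2]])
    return _normalize_pure(b)


def _normalize_pure(p: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(p[1:])
    if n < 1e-12:
        raise ValueError("degenerate reference direction")
    out = p.copy()
    out[1:] /= n
    return out


def _gradient(q: np.ndarray, a: np.ndarray, m: np.ndarray | None) -> np.ndarray:
    """Stacked-objective gradient ∇f = Σ Jᵀ f over gravity (+ magnetic)."""
    a_hat = np.concatenate([[0.0], a / np.linalg.norm(a)])
    f = objective(q, GRAVITY_REF, a_hat)
    grad = objective_jacobian(q, GRAVITY_REF).T @ f
    if m is not None:
        b = magnetic_reference(q, m)
        m_hat = np.concatenate([[0.0], m / np.linalg.norm(m)])
        fb = objective(q, b, m_hat)
        grad = grad + objective_jacobian(q, b).T @ fb
    return grad


def madgwick_update(
    q_prev: np.ndarray,
    omega: np.ndarray,
    accel: np.ndarray,
    mag: np.ndarray | None,
    cfg: AhrsConfig,
    gain: float | None = None,
    gated: bool = False,
) -> tuple[np.ndarray, bool]:
    """One fused filter step.

    Returns ``(q, corrected)`` where ``corrected`` is False when no
    gradient correction was applied (unusable accelerometer sample, motion
    gate, or ``beta=0``) and the step fell back to gyroscope propagation.

    ``gain`` overrides ``cfg.beta`` for this step (used by the
    accelerated-initialization schedule); ``gated`` suspends the correction
    (set by :func:`run_ahrs` from the dilated motion-gate mask).
    """
    beta = cfg.beta if gain is None else gain
    dt = cfg.sample_period
    q_prev = np.asarray(q_prev, dtype=float)
    omega = np.asarray(omega, dtype=float)
    accel = np.asarray(accel, dtype=float)
    qdot = 0.5 * qm.multiply(q_prev, np.concatenate([[0.0], omega]))
    corrected = False
    if beta > 0 and not gated and np.linalg.norm(accel) > 1e-12:
        m = mag if (cfg.use_magnetometer and mag is not None) else None
        grad = _gradient(q_prev, accel, m)
        gnorm = np.linalg.norm(grad)
        if gnorm > 1e-15:
            qdot = qdot - beta * cfg.mu * (grad / gnorm)
            corrected = True
    return qm.normalize(q_prev + qdot * dt), corrected


def run_ahrs(
    omega: np.ndarray,
    accel: np.ndarray,
    mag: np.ndarray | None,
    cfg: AhrsConfig,
) -> np.ndarray:
    """Run the fused filter over aligned sample tracks.

    Parameters
    ----------
    omega, accel:
        (n, 3) arrays on one uniform time base (rad·s⁻¹, m·s⁻²).
    mag:
        (n, 3) array in µT, or None for IMU-only operation.  Lower-rate
        magnetometers must be sample-and-held onto the common grid upstream
        (see :mod:`frtkit.preprocess`).
    cfg:
        Filter configuration; ``cfg.sample_period`` is the grid spacing.

    Returns
    -------
    (n, 4) array of unit quaternions, one per sample; element ``i`` is the
    estimate after processing sample ``i``.
    """
    omega = np.asarray(omega, dtype=float)
    accel = np.asarray(accel, dtype=float)
    if omega.shape != accel.shape or omega.ndim != 2 or omega.shape[1] != 3:
        raise ValueError("omega and accel must be matching (n, 3) arrays")
    if mag is not None:
        mag = np.asarray(mag, dtype=float)
        if mag.shape != omega.shape:
            raise ValueError("mag must match omega/accel in shape")
    n = omega.shape[0]
    out = np.empty((n, 4))
    q = qm.normalize(cfg.initial_q)
    n_init = 0
    if cfg.init_gain is not None and cfg.beta > 0:
        n_init = int(round(cfg.init_time_s / cfg.sample_period))
    gate_mask = np.zeros(n, dtype=bool)
    if cfg.motion_gate_rad_s is not None:
        fast = np.linalg.norm(omega, axis=1) > cfg.motion_gate_rad_s
        half = int(round(cfg.motion_gate_dilate_s / cfg.sample_period))
        if half > 0 and np.any(fast):
            kernel = np.ones(2 * half + 1)
            fast = np.convolve(fast.astype(float), kernel, mode="same") > 0
        gate_mask = fast
    for i in range(n):
        gain = cfg.init_gain if i < n_init else None
        q, _ = madgwick_update(
            q,
            omega[i],
            accel[i],
            None if mag is None else mag[i],
            cfg,
            gain=gain,
            gated=bool(gate_mask[i]),
        )
        out[i] = q
    return out
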