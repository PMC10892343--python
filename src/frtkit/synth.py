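"""Synthetic FRT MARG-stream generator with ground truth.

The generator emulates a smartphone strapped to the upper arm of a subject
performing functional reach tests: quiet standing, then one or more
lean-and-return movements of known horizontal extent, sampled like the
target hardware (nominal 400 Hz accelerometer/gyroscope, 100 Hz
magnetometer, millisecond-level timestamp jitter).

Movement model
--------------
A hip-hinge: the sensor sits at the end of a rigid lever arm of length
``sensor_height_m`` anchored at the hips.  The lean angle follows a
minimum-jerk profile from upright to the angle whose horizontal lever-arm
excursion equals ``reach_m``, then returns the same way.  The sensor frame
rotates rigidly with the lever, starting aligned with the ENU Earth frame.
All emitted signals derive analytically from this one trajectory, so the
ground-truth orientation, position, and per-attempt reach are exact:

* gyroscope — body rates (the lean-rate about the fixed horizontal axis)
  plus a constant per-axis bias and white noise;
* accelerometer — the specific force ``Rᵀ(p̈ + g)`` plus white noise;
* magnetometer — the Earth field (horizontal component toward geomagnetic
  north, vertical component pointing down, mid-latitude magnitudes) rotated
  into the sensor frame, plus white noise.

Everything is deterministic under a fixed ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import quatmath as qm
from .preprocess import SensorStream

__all__ = ["SynthConfig", "SynthTruth", "simulate_frt_trial", "simulate_static"]


@dataclass
class SynthConfig:
    """Simulator parameters (SI units unless noted)."""

    reach_m: float = 0.20  # true horizontal reach per attempt
    lean_duration_s: float = 2.0  # per extension (and per return)
    n_attempts: int = 2
    pre_quiet_s: float = 10.0
    inter_quiet_s: float = 10.0
    sensor_height_m: float = 0.60  # hip-to-armband lever arm
    heading_deg: float = 0.0  # reach direction, degrees from east
    acc_rate_hz: float = 400.0
    gyro_rate_hz: float = 400.0
    mag_rate_hz: float = 100.0
    timestamp_jitter_ms: float = 1.0
    acc_noise_std: float = 0.05  # m·s⁻²
    gyro_noise_std: float = 0.005  # rad·s⁻¹
    mag_noise_std: float = 0.5  # µT
    gyro_bias: float = 0.01  # rad·s⁻¹, applied on every axis
    mag_field_ut: tuple[float, float] = (22.0, -40.0)  # (horizontal N, vertical)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reach_m <= 0:
            raise ValueError("reach_m must be positive")
        if min(self.acc_rate_hz, self.gyro_rate_hz, self.mag_rate_hz) <= 0:
            raise ValueError("sampling rates must be positive")
        if self.n_attempts < 1:
            raise ValueError("n_attempts must be at least 1")
        if self.reach_m > self.sensor_height_m:
            raise ValueError("reach_m cannot exceed the lever arm length")

    @property
    def duration_s(self) -> float:
        return self.pre_quiet_s + self.n_attempts * (
            2 * self.lean_duration_s + self.inter_quiet_s
        )


@dataclass
class SynthTruth:
    """Ground truth emitted alongside the synthetic streams."""

    t_s: np.ndarray  # accelerometer/gyroscope time base, seconds
    orientation: np.ndarray  # (n, 4) unit quaternions, sensor → Earth
    position_E: np.ndarray  # (n, 3) metres, relative to start
    reach_cm: list[float] = field(default_factory=list)  # per attempt
    attempt_centers_s: list[float] = field(default_factory=list)


def _minjerk(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum-jerk position profile s(τ) on [0, 1] with s', s''."""
    tau = np.clip(tau, 0.0, 1.0)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    ds = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    dds = 60 * tau - 180 * tau**2 + 120 * tau**3
    return s, ds, dds


def _lean_profile(cfg: SynthConfig, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lean angle α(t) with first and second time derivatives."""
    alpha_max = np.arcsin(cfg.reach_m / cfg.sensor_height_m)
    T = cfg.lean_duration_s
    alpha = np.zeros_like(t)
    dalpha = np.zeros_like(t)
    ddalpha = np.zeros_like(t)
    for i in range(cfg.n_attempts):
        start = cfg.pre_quiet_s + i * (2 * T + cfg.inter_quiet_s)
        up = (t >= start) & (t < start + T)
        down = (t >= start + T) & (t <= start + 2 * T)
        s, ds, dds = _minjerk((t[up] - start) / T)
        alpha[up] = alpha_max * s
        dalpha[up] = alpha_max * ds / T
        ddalpha[up] = alpha_max * dds / T**2
        s, ds, dds = _minjerk(1.0 - (t[down] - start - T) / T)
        alpha[down] = alpha_max * s
        dalpha[down] = -alpha_max * ds / T
        ddalpha[down] = alpha_max * dds / T**2
    return alpha, dalpha, ddalpha


def _axes(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    h = np.radians(cfg.heading_deg)
    d = np.array([np.cos(h), np.sin(h), 0.0])  # reach direction
    a = np.array([-np.sin(h), np.cos(h), 0.0])  # lean rotation axis (ẑ × d)
    return d, a


def truth_at(cfg: SynthConfig, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact (orientation, position) of the reach trajectory at times ``t``."""
    t = np.asarray(t, dtype=float)
    d, axis = _axes(cfg)
    alpha, _, _ = _lean_profile(cfg, t)
    L = cfg.sensor_height_m
    q = qm.from_axis_angle(axis, alpha)
    pos = L * np.sin(alpha)[:, None] * d + L * (np.cos(alpha) - 1.0)[:, None] * np.array(
        [0.0, 0.0, 1.0]
    )
    return q, pos


def _jittered_times(rng: np.random.Generator, duration: float, rate: float, jitter_ms: float) -> np.ndarray:
    dt = 1.0 / rate
    n = int(np.ceil(duration * rate)) + 1
    j = min(jitter_ms * 1e-3, 0.4 * dt)
    steps = dt + rng.uniform(-j, j, size=n - 1)
    t = np.concatenate([[0.0], np.cumsum(steps)])
    return t[t <= duration + dt / 2]


def _make_stream(kind: str, t: np.ndarray, values: np.ndarray) -> SensorStream:
    return SensorStream(kind=kind, t_ns=np.round(t * 1e9).astype(np.int64), values=values)


def simulate_frt_trial(cfg: SynthConfig) -> tuple[dict[str, SensorStream], SynthTruth]:
    """Generate one synthetic FRT assessment.

    Returns a dict of streams keyed ``{"acc", "gyr", "mag"}`` plus the
    software-style derived streams ``{"gra", "lin", "rot"}`` computed from
    the exact trajectory, and the ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    duration = cfg.duration_s
    t_acc = _jittered_times(rng, duration, cfg.acc_rate_hz, cfg.timestamp_jitter_ms)
    t_gyr = t_acc if cfg.gyro_rate_hz == cfg.acc_rate_hz else _jittered_times(
        rng, duration, cfg.gyro_rate_hz, cfg.timestamp_jitter_ms
    )
    t_mag = _jittered_times(rng, duration, cfg.mag_rate_hz, cfg.timestamp_jitter_ms)

    d, axis = _axes(cfg)
    L = cfg.sensor_height_m
    zhat = np.array([0.0, 0.0, 1.0])
    g = np.array([0.0, 0.0, 9.81])
    b_E = np.array([0.0, cfg.mag_field_ut[0], cfg.mag_field_ut[1]])

    q_acc, pos = truth_at(cfg, t_acc)
    alpha, dalpha, ddalpha = _lean_profile(cfg, t_acc)
    accel_E = (
        L * (np.cos(alpha) * ddalpha - np.sin(alpha) * dalpha**2)[:, None] * d
        - L * (np.sin(alpha) * ddalpha + np.cos(alpha) * dalpha**2)[:, None] * zhat
    )
    q_conj = qm.conjugate(q_acc)
    acc_S = qm.rotate_vector(q_conj, accel_E + g)
    grav_S = qm.rotate_vector(q_conj, g)
    lin_S = acc_S - grav_S
    acc_S = acc_S + rng.normal(0.0, cfg.acc_noise_std, acc_S.shape) if cfg.acc_noise_std else acc_S

    _, dalpha_g, _ = _lean_profile(cfg, t_gyr)
    gyr_S = dalpha_g[:, None] * axis
    if cfg.gyro_bias:
        gyr_S = gyr_S + cfg.gyro_bias
    if cfg.gyro_noise_std:
        gyr_S = gyr_S + rng.normal(0.0, cfg.gyro_noise_std, gyr_S.shape)

    q_mag, _ = truth_at(cfg, t_mag)
    mag_S = qm.rotate_vector(qm.conjugate(q_mag), np.broadcast_to(b_E, (len(t_mag), 3)))
    if cfg.mag_noise_std:
        mag_S = mag_S + rng.normal(0.0, cfg.mag_noise_std, mag_S.shape)

    # rotation-vector stream mirrors Android layout: X, Y, Z then scalar
    rot_vals = np.column_stack([q_acc[:, 1], q_acc[:, 2], q_acc[:, 3], q_acc[:, 0]])

    streams = {
        "acc": _make_stream("accelerometer", t_acc, acc_S),
        "gyr": _make_stream("gyroscope", t_gyr, gyr_S),
        "mag": _make_stream("magnetometer", t_mag, mag_S),
        "gra": _make_stream("gravity", t_acc, grav_S),
        "lin": _make_stream("linear_acceleration", t_acc, lin_S),
        "rot": _make_stream("rotation_vector", t_acc, rot_vals),
    }
    T = cfg.lean_duration_s
    centers = [
        cfg.pre_quiet_s + i * (2 * T + cfg.inter_quiet_s) + T for i in range(cfg.n_attempts)
    ]
    truth = SynthTruth(
        t_s=t_acc,
        orientation=q_acc,
        position_E=pos,
        reach_cm=[100.0 * cfg.reach_m] * cfg.n_attempts,
        attempt_centers_s=centers,
    )
    return streams, truth


def simulate_static(
    duration_s: float,
    tilt_deg: tuple[float, float, float] = (0.0, 0.0, 0.0),
    cfg: SynthConfig | None = None,
) -> tuple[dict[str, SensorStream], SynthTruth]:
    """Constant-orientation streams for fusion convergence/accuracy tests.

    ``tilt_deg`` is (roll, pitch, yaw) of the fixed sensor orientation.
    Noise, biases, rates, and seed come from ``cfg`` (defaults used when
    None; the movement-profile fields are ignored).
    """
    cfg = cfg if cfg is not None else SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    t_acc = _jittered_times(rng, duration_s, cfg.acc_rate_hz, cfg.timestamp_jitter_ms)
    t_mag = _jittered_times(rng, duration_s, cfg.mag_rate_hz, cfg.timestamp_jitter_ms)

    q = qm.from_euler(*tilt_deg)
    g = np.array([0.0, 0.0, 9.81])
    b_E = np.array([0.0, cfg.mag_field_ut[0], cfg.mag_field_ut[1]])
    n_a, n_m = len(t_acc), len(t_mag)

    grav_S = qm.rotate_vector(qm.conjugate(q), g)
    acc_S = np.broadcast_to(grav_S, (n_a, 3)).copy()
    if cfg.acc_noise_std:
        acc_S += rng.normal(0.0, cfg.acc_noise_std, acc_S.shape)
    gyr_S = np.full((n_a, 3), cfg.gyro_bias, dtype=float)
    if cfg.gyro_noise_std:
        gyr_S += rng.normal(0.0, cfg.gyro_noise_std, gyr_S.shape)
    mag_S = np.broadcast_to(qm.rotate_vector(qm.conjugate(q), b_E), (n_m, 3)).copy()
    if cfg.mag_noise_std:
        mag_S += rng.normal(0.0, cfg.mag_noise_std, mag_S.shape)

    q_track = np.broadcast_to(q, (n_a, 4)).copy()
    rot_vals = np.column_stack([q_track[:, 1], q_track[:, 2], q_track[:, 3], q_track[:, 0]])
    streams = {
        "acc": _make_stream("accelerometer", t_acc, acc_S),
        "gyr": _make_stream("gyroscope", t_acc, gyr_S),
        "mag": _make_stream("magnetometer", t_mag, mag_S),
        "gra": _make_stream("gravity", t_acc, np.broadcast_to(grav_S, (n_a, 3)).copy()),
        "lin": _make_stream("linear_acceleration", t_acc, np.zeros((n_a, 3))),
        "rot": _make_stream("rotation_vector", t_acc, rot_vals),
    }
    truth = SynthTruth(
        t_s=t_acc,
        orientation=q_track,
        position_E=np.zeros((n_a, 3)),
        reach_cm=[],
        attempt_centers_s=[],
    )
    return streams, truth
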