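"""End-to-end assessment processing: streams → orientation → reach report.

This is the wiring layer the command-line interface and the tests share:

1. resample accelerometer and gyroscope onto a common uniform 100 Hz grid
   (cubic splines), sample-and-hold the magnetometer onto the same grid;
2. run the gradient-descent MARG fusion to get the orientation track;
3. locate movement windows on the gravity-filtered acceleration;
4. per window: rotate the accelerometer into the Earth frame, remove
   gravity, double-integrate with drift filtering, and extract the reach
   distance along the principal horizontal direction.

Each window is integrated independently from zero initial velocity: the
subject stands still between attempts, so the per-window assumption of rest
at the window edge holds by protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from . import frt, kinematics, quatmath as qm
from .fusion import AhrsConfig, run_ahrs
from .kinematics import ReachResult
from .preprocess import (
    DRIFT_FILTER,
    GRAVITY_FILTER,
    FilterSpec,
    MovementWindow,
    SensorStream,
    detect_movement_windows,
    highpass_gravity,
    hold_to_grid,
    resample_uniform,
)

__all__ = ["AssessmentReport", "align_streams", "estimate_orientation", "estimate_assessment"]

DEFAULT_RATE_HZ = 100.0


@dataclass
class AssessmentReport:
    """Result of one assessment run through the full pipeline."""

    reaches: list[ReachResult]
    risk: list[frt.RiskClass]
    windows: list[MovementWindow]
    summary: frt.AssessmentSummary | None = None
    t_grid: np.ndarray | None = None
    orientation: np.ndarray | None = None

    @property
    def estimated_cm(self) -> list[float]:
        return [r.distance_cm for r in self.reaches]


def align_streams(
    acc: SensorStream,
    gyr: SensorStream,
    mag: SensorStream | None,
    rate: float = DEFAULT_RATE_HZ,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
    """Put the three sensor tracks on one uniform time grid.

    The grid derives from the accelerometer span.  Accelerometer and
    gyroscope are spline-interpolated; the magnetometer (lower-rate) is
    sample-and-held, never interpolated.
    """
    acc_u = resample_uniform(acc, rate)
    t_grid = acc_u.t_s
    gyr_vals = CubicSpline(gyr.t_s, gyr.values, axis=0)(t_grid)
    mag_vals = hold_to_grid(mag, t_grid) if mag is not None else None
    return t_grid, acc_u.values, gyr_vals, mag_vals


def estimate_orientation(
    acc: SensorStream,
    gyr: SensorStream,
    mag: SensorStream | None,
    rate: float = DEFAULT_RATE_HZ,
    cfg: AhrsConfig | None = None,
    debias_gyro: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fused orientation track on the uniform grid.

    With ``debias_gyro`` (default) the per-axis median of the gyroscope
    track is removed first — a static bias calibration.  The FRT protocol
    is mostly quiet standing, so the median is a robust estimate of the
    constant rate offset that would otherwise integrate into a tilt error
    whenever the gravity correction is suspended.

    Returns ``(t_grid, quaternions, accel_on_grid)``.
    """
    t_grid, acc_vals, gyr_vals, mag_vals = align_streams(acc, gyr, mag, rate)
    if debias_gyro:
        gyr_vals = gyr_vals - np.median(gyr_vals, axis=0)
    if cfg is None:
        cfg = AhrsConfig(sample_period=1.0 / rate, use_magnetometer=mag is not None)
    q = run_ahrs(gyr_vals, acc_vals, mag_vals, cfg)
    return t_grid, q, acc_vals


def estimate_assessment(
    acc: SensorStream,
    gyr: SensorStream,
    mag: SensorStream | None = None,
    manual_frt_cm: list[float] | None = None,
    rate: float = DEFAULT_RATE_HZ,
    ahrs_cfg: AhrsConfig | None = None,
    gravity_filter: FilterSpec = GRAVITY_FILTER,
    drift_filter: FilterSpec = DRIFT_FILTER,
) -> AssessmentReport:
    """Run the full reach-estimation pipeline on one assessment."""
    t_grid, q, acc_vals = estimate_orientation(acc, gyr, mag, rate, ahrs_cfg)
    acc_grid = SensorStream(
        kind="accelerometer", t_ns=np.round(t_grid * 1e9).astype(np.int64), values=acc_vals
    )
    filtered = highpass_gravity(acc_grid, gravity_filter)
    windows = detect_movement_windows(filtered)

    accel_E = kinematics.earth_linear_accel(q, acc_vals)
    reaches: list[ReachResult] = []
    for win in windows:
        mask = (t_grid >= win.start - 1e-9) & (t_grid <= win.end + 1e-9)
        pose = kinematics.integrate_position(
            accel_E[mask], rate, drift_filter, t0=float(t_grid[mask][0])
        )
        reaches.append(kinematics.reach_distance(pose, win))

    risk = [frt.classify_risk(r.distance_cm) for r in reaches]
    summary = None
    if manual_frt_cm:
        n = min(len(reaches), len(manual_frt_cm))
        if n > 0:
            trials = [
                frt.TrialEstimate(reaches[i].distance_cm, manual_frt_cm[i]) for i in range(n)
            ]
            summary = frt.summarize_assessment(trials)
    return AssessmentReport(
        reaches=reaches, risk=risk, windows=windows, summary=summary, t_grid=t_grid, orientation=q
    )


def benchmark_against_reference(
    acc: SensorStream,
    gyr: SensorStream,
    mag: SensorStream | None,
    reference_q: np.ndarray,
    reference_t: np.ndarray,
    rate: float = DEFAULT_RATE_HZ,
    cfg: AhrsConfig | None = None,
    warmup_s: float = 1.0,
    yaw_offset_deg: float = 90.0,
) -> frt.BenchmarkReport:
    """Euler-angle benchmark of the fused estimate against a reference
    quaternion track (e.g. the device rotation vector).

    The reference is nearest-neighbour matched onto the estimation grid,
    the convergence warm-up is excluded, and the standard 90° yaw offset of
    the x-axis magnetic reference is removed before computing the metrics.
    """
    t_grid, q, _ = estimate_orientation(acc, gyr, mag, rate, cfg)
    idx = np.clip(np.searchsorted(reference_t, t_grid), 0, len(reference_t) - 1)
    ref_q = np.asarray(reference_q)[idx]
    keep = t_grid >= t_grid[0] + warmup_s
    est_e = qm.to_euler(q[keep])
    ref_e = qm.to_euler(qm.normalize(ref_q[keep]))
    return frt.benchmark_orientation(est_e, ref_e, yaw_offset_deg)
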