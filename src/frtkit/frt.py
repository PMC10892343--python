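"""Functional Reach Test metrics, fall-risk classification, and orientation
benchmarking.

The FRT reach distance stratifies fall risk in older adults:

* reach > 25.40 cm — negative test, low fall risk;
* 15.24 cm ≤ reach ≤ 25.40 cm — doubled fall risk over six months;
* reach < 15.24 cm — quadrupled fall risk over six months.

Age- and sex-stratified reference (norm) values are provided for adults of
20-87 years.  Assessment summaries average the estimated and manually
measured reach over the trials of one assessment and report the absolute
difference of those averages as the assessment error.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

import numpy as np

__all__ = [
    "TrialEstimate",
    "AssessmentSummary",
    "RiskClass",
    "BenchmarkReport",
    "error_metrics",
    "classify_risk",
    "norm_value",
    "summarize_assessment",
    "benchmark_orientation",
    "wrap_degrees",
]


class RiskClass(Enum):
    LOW_RISK = "low_risk"
    DOUBLE_RISK = "double_risk"
    QUADRUPLE_RISK = "quadruple_risk"


# Reach norms (cm) by age band and sex, adults 20-87 years.
NORM_TABLE_CM = {
    (20, 40): {"male": 42.49, "female": 37.19},
    (41, 69): {"male": 38.25, "female": 35.08},
    (70, 87): {"male": 33.43, "female": 26.59},
}

LOW_RISK_THRESHOLD_CM = 25.40
QUADRUPLE_RISK_THRESHOLD_CM = 15.24


@dataclass(frozen=True)
class TrialEstimate:
    """One FRT trial: pipeline estimate vs. manual ruler measurement."""

    estimated_cm: float
    measured_cm: float

    def __post_init__(self) -> None:
        if self.estimated_cm < 0 or self.measured_cm < 0:
            raise ValueError("reach distances must be non-negative")


@dataclass(frozen=True)
class AssessmentSummary:
    avg_estimated_cm: float
    avg_measured_cm: float
    avg_error_cm: float


@dataclass(frozen=True)
class BenchmarkReport:
    """Per-Euler-angle agreement of an orientation estimate with a reference.

    MAE and RMSE in degrees, MSE in squared degrees; rows are roll, pitch,
    yaw.
    """

    mae_deg: np.ndarray
    mse_deg2: np.ndarray
    rmse_deg: np.ndarray

    ANGLES = ("roll", "pitch", "yaw")

    def as_table(self) -> str:
        lines = [f"{'angle':<8}{'MAE':>10}{'MSE':>12}{'RMSE':>10}"]
        for i, name in enumerate(self.ANGLES):
            lines.append(
                f"{name:<8}{self.mae_deg[i]:>10.3f}{self.mse_deg2[i]:>12.3f}{self.rmse_deg[i]:>10.3f}"
            )
        return "\n".join(lines)


def error_metrics(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """(MAE, MSE, RMSE) of predictions ``y`` against truth ``x``.

    MAE = Σ|yᵢ−xᵢ|/n, MSE = Σ(yᵢ−xᵢ)²/n, RMSE = √MSE.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("sequences must have equal length")
    if y.size == 0:
        raise ValueError("sequences must be non-empty")
    d = y - x
    mae = float(np.mean(np.abs(d)))
    mse = float(np.mean(d * d))
    return mae, mse, float(np.sqrt(mse))


def classify_risk(reach_cm: float) -> RiskClass:
    """Fall-risk class of a reach distance in cm.

    The boundaries themselves fall in the doubled-risk band: "exceeds
    25.40" is strict, and the doubled-risk range is inclusive on both ends.
    """
    if reach_cm < 0:
        raise ValueError("reach distance must be non-negative")
    if reach_cm > LOW_RISK_THRESHOLD_CM:
        return RiskClass.LOW_RISK
    if reach_cm >= QUADRUPLE_RISK_THRESHOLD_CM:
        return RiskClass.DOUBLE_RISK
    return RiskClass.QUADRUPLE_RISK


def norm_value(age_years: int, sex: str) -> float:
    """Reference reach (cm) for an adult of the given age and sex.

    Bands: 20-40, 41-69, 70-87 years.  Ages outside 20-87 raise (the
    reference table does not support extrapolation).
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    for (lo, hi), values in NORM_TABLE_CM.items():
        if lo <= age_years <= hi:
            return values[sex]
    raise ValueError(f"age {age_years} outside the 20-87 year reference range")


def summarize_assessment(trials: list[TrialEstimate]) -> AssessmentSummary:
    """Assessment-level summary of per-trial reach results.

    Averages the estimated and measured columns; the assessment error is
    the absolute difference of the two averages (not the mean per-trial
    error).  Values rounded to 2 decimals for reporting.
    """
    if not trials:
        raise ValueError("at least one trial is required")
    est = float(np.mean([t.estimated_cm for t in trials]))
    meas = float(np.mean([t.measured_cm for t in trials]))
    # the error difference is taken in decimal space: binary-float
    # subtraction of cm values produces representation noise that flips the
    # half-up rounding of the second decimal
    err = abs(Decimal(repr(est)) - Decimal(repr(meas)))
    return AssessmentSummary(
        avg_estimated_cm=_round2(est),
        avg_measured_cm=_round2(meas),
        avg_error_cm=float(err.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)),
    )


def _round2(x: float) -> float:
    """Round to 2 decimals with decimal half-up (clinical-table convention,
    not binary-float banker's rounding)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def wrap_degrees(angle: np.ndarray) -> np.ndarray:
    """Wrap angle(s) into (−180°, 180°]."""
    return -(np.mod(-np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0)


def benchmark_orientation(
    estimate_deg: np.ndarray,
    reference_deg: np.ndarray,
    yaw_offset_deg: float = 90.0,
) -> BenchmarkReport:
    """Per-angle error metrics of an Euler-angle track against a reference.

    ``estimate_deg`` and ``reference_deg`` are (n, 3) arrays of (roll,
    pitch, yaw) in degrees.  ``yaw_offset_deg`` is subtracted from the
    reference yaw before comparison: an estimator whose magnetic reference
    collapses the horizontal field onto the Earth *x* axis reports yaw 90°
    off a true-north (ENU y) reference such as the device rotation vector.
    All differences are wrapped into (−180°, 180°] so seam crossings do not
    corrupt the statistics; convergence warm-up should be excluded upstream.
    """
    est = np.atleast_2d(np.asarray(estimate_deg, dtype=float))
    ref = np.atleast_2d(np.asarray(reference_deg, dtype=float)).copy()
    if est.shape != ref.shape:
        raise ValueError("estimate and reference must have equal shape")
    ref[:, 2] = wrap_degrees(ref[:, 2] - yaw_offset_deg)
    diffs = wrap_degrees(est - ref)
    mae = np.mean(np.abs(diffs), axis=0)
    mse = np.mean(diffs * diffs, axis=0)
    return BenchmarkReport(mae_deg=mae, mse_deg2=mse, rmse_deg=np.sqrt(mse))
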