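"""Sensor-stream container, resampling, gravity filtering, and movement
segmentation.

Mobile MARG recordings arrive with irregular timestamps (nominal 400 Hz for
the inertial sensors, 100 Hz for the magnetometer, with millisecond-level
jitter).  The pipeline first resamples every stream onto a uniform 100 Hz
grid by cubic-spline interpolation, removes the gravitational component of
the acceleration with a high-order FIR high-pass filter, and finally locates
the reach movements as bursts of the filtered-acceleration envelope; each
burst yields a fixed 5-second analysis window centred on it.

All filtering here is zero-phase (forward-backward), so filtered streams
stay aligned with their timestamps and no group-delay bookkeeping leaks into
the downstream distance extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, firwin, sosfiltfilt

__all__ = [
    "SensorStream",
    "MovementWindow",
    "FilterSpec",
    "resample_uniform",
    "highpass_gravity",
    "apply_filter",
    "detect_movement_windows",
    "hold_to_grid",
]

KIND_UNITS = {
    "accelerometer": "m·s⁻²",
    "gyroscope": "rad·s⁻¹",
    "magnetometer": "µT",
    "gravity": "m·s⁻²",
    "linear_acceleration": "m·s⁻²",
    "rotation_vector": "unitless",
}


@dataclass
class SensorStream:
    """Timestamped triaxial samples of one sensor kind.

    The nanosecond sensor timestamp is authoritative for all signal
    processing (``t_s`` derives from it); the millisecond system timestamp
    is retained as metadata only.  ``values`` is (n, 3), or (n, 4) for the
    rotation-vector stream.
    """

    kind: str
    t_ns: np.ndarray
    values: np.ndarray
    t_ms: np.ndarray | None = None
    raw: bool = False
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KIND_UNITS:
            raise ValueError(f"unknown sensor kind {self.kind!r}")
        self.t_ns = np.asarray(self.t_ns)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.t_ns) != len(self.values):
            raise ValueError("value rows must equal timestamp count")
        dt = np.diff(self.t_ns.astype(np.int64))
        if np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0))
            raise ValueError(f"timestamps not strictly increasing at index {idx + 1}")
        if not self.units:
            self.units = KIND_UNITS[self.kind]
        if self.t_ms is None:
            self.t_ms = (self.t_ns.astype(np.int64) // 1_000_000).astype(np.int64)

    @property
    def t_s(self) -> np.ndarray:
        """Seconds from the first sample (float64)."""
        t0 = self.t_ns.astype(np.int64)[0]
        return (self.t_ns.astype(np.int64) - t0) * 1e-9 + t0 * 1e-9

    def __len__(self) -> int:
        return len(self.t_ns)


@dataclass(frozen=True)
class MovementWindow:
    """A 5-second analysis window, seconds from the recording start."""

    start: float
    end: float
    clipped: bool = False

    @property
    def width(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class FilterSpec:
    """High-pass filter description (FIR or Butterworth)."""

    family: str = "FIR"  # "FIR" | "Butterworth"
    order: int = 1000
    cutoff_hz: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("FIR", "Butterworth"):
            raise ValueError("family must be 'FIR' or 'Butterworth'")
        if self.order <= 0:
            raise ValueError("order must be positive")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff must be positive")


GRAVITY_FILTER = FilterSpec("FIR", 1000, 1.0)
DRIFT_FILTER = FilterSpec("Butterworth", 5, 0.01)


def resample_uniform(stream: SensorStream, rate: float) -> SensorStream:
    """Cubic-spline resampling onto a uniform grid at ``rate`` Hz.

    The grid spans ``[t_first, t_last]`` with spacing exactly ``1/rate``.
    Cubic splines reproduce polynomials up to degree 3 exactly, so smooth
    signals survive the jittered-to-uniform transfer with negligible error.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if len(stream) < 4:
        raise ValueError("need at least 4 samples for cubic-spline resampling")
    t = stream.t_s
    n_out = int(np.floor((t[-1] - t[0]) * rate + 1e-9)) + 1
    t_new = t[0] + np.arange(n_out) / rate
    spline = CubicSpline(t, stream.values, axis=0)
    vals = spline(t_new)
    t_ns = np.round(t_new * 1e9).astype(np.int64)
    # re-spacing may round to equal ns at extreme rates; keep it strict
    return replace(stream, t_ns=t_ns, values=vals, t_ms=None)


def _fir_taps(spec: FilterSpec, rate: float) -> np.ndarray:
    nyq = rate / 2.0
    if not spec.cutoff_hz < nyq:
        raise ValueError("cutoff must be below the Nyquist frequency")
    return firwin(spec.order + 1, spec.cutoff_hz, fs=rate, pass_zero=False)


def apply_filter(x: np.ndarray, spec: FilterSpec, rate: float) -> np.ndarray:
    """Zero-phase high-pass filtering of (n,) or (n, k) data at ``rate`` Hz."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if spec.family == "FIR":
        if n <= 3 * spec.order:
            raise ValueError(
                f"stream of {n} samples too short for zero-phase FIR of order {spec.order}"
            )
        taps = _fir_taps(spec, rate)
        return filtfilt(taps, [1.0], x, axis=0)
    sos = butter(spec.order, spec.cutoff_hz, btype="highpass", fs=rate, output="sos")
    return sosfiltfilt(sos, x, axis=0)


def highpass_gravity(stream: SensorStream, spec: FilterSpec = GRAVITY_FILTER) -> SensorStream:
    """Remove the gravitational (DC/near-DC) component of an acceleration
    stream with a zero-phase FIR high-pass filter.

    The stream must already be on a uniform grid (see
    :func:`resample_uniform`) and longer than three filter orders.
    """
    t = stream.t_s
    dt = np.diff(t)
    rate = 1.0 / np.median(dt)
    if np.max(np.abs(dt - 1.0 / rate)) > 0.1 / rate:
        raise ValueError("highpass_gravity requires a uniform-rate stream")
    vals = apply_filter(stream.values, spec, rate)
    return replace(stream, values=vals, kind="linear_acceleration", units=KIND_UNITS["linear_acceleration"])


def _moving_rms(x: np.ndarray, n: int) -> np.ndarray:
    kernel = np.ones(n) / n
    power = np.convolve(x * x, kernel, mode="same")
    return np.sqrt(np.maximum(power, 0.0))


def detect_movement_windows(
    stream: SensorStream,
    window_s: float = 5.0,
    envelope_s: float = 0.5,
    threshold_factor: float = 4.0,
    band_limit_hz: float | None = 2.5,
) -> list[MovementWindow]:
    """Locate reach movements in a gravity-filtered acceleration stream.

    A moving-RMS envelope (default 0.5 s) of the acceleration magnitude is
    thresholded at ``threshold_factor`` times its median; each
    above-threshold burst yields one window of ``window_s`` seconds centred
    on the burst's envelope centroid.  Bursts closer than ``window_s`` are
    merged.  Windows that would extend past the recording are clipped and
    flagged rather than discarded.

    Voluntary reach movements live below a few hertz while sensor noise is
    broadband, so the signal is low-pass filtered at ``band_limit_hz``
    (zero-phase) before the envelope is formed; this lifts the burst
    envelope well clear of the noise floor without moving its centroid.
    """
    t = stream.t_s
    dt = np.median(np.diff(t))
    rate = 1.0 / dt
    vals = stream.values[:, :3]
    if band_limit_hz is not None and band_limit_hz < rate / 2:
        sos = butter(4, band_limit_hz, btype="lowpass", fs=rate, output="sos")
        vals = sosfiltfilt(sos, vals, axis=0)
    mag = np.linalg.norm(vals, axis=1)
    env = _moving_rms(mag, max(1, int(round(envelope_s * rate))))
    thresh = threshold_factor * np.median(env)
    active = env > thresh
    if not np.any(active):
        return []
    # contiguous above-threshold runs
    idx = np.flatnonzero(active)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    # merge runs whose centroids are closer than window_s
    centers = []
    for run in runs:
        w = env[run]
        centers.append(float(np.sum(t[run] * w) / np.sum(w)))
    merged: list[list[int]] = [[0]]
    for i in range(1, len(runs)):
        if centers[i] - centers[merged[-1][-1]] < window_s:
            merged[-1].append(i)
        else:
            merged.append([i])
    windows = []
    for group in merged:
        run = np.concatenate([runs[i] for i in group])
        w = env[run]
        c = float(np.sum(t[run] * w) / np.sum(w))
        start, end = c - window_s / 2, c + window_s / 2
        clipped = False
        if start < t[0]:
            start, end, clipped = t[0], min(t[0] + window_s, t[-1]), True
        if end > t[-1]:
            start, end, clipped = max(t[-1] - window_s, t[0]), t[-1], True
        windows.append(MovementWindow(start, end, clipped))
    return windows


def hold_to_grid(stream: SensorStream, t_grid: np.ndarray) -> np.ndarray:
    """Sample-and-hold a (possibly lower-rate) stream onto a time grid.

    Each grid point takes the most recent sample at or before it; grid
    points before the first sample take the first sample.  Used for the
    magnetometer, which is never interpolated.
    """
    t = stream.t_s
    idx = np.searchsorted(t, np.asarray(t_grid) + 1e-12, side="right") - 1
    idx = np.clip(idx, 0, len(t) - 1)
    return stream.values[idx]
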