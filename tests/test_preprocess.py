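"""Resampling, gravity filtering, and movement segmentation."""

import numpy as np
import pytest

from conftest import make_uniform_stream
from frtkit.preprocess import (
    FilterSpec,
    SensorStream,
    detect_movement_windows,
    highpass_gravity,
    hold_to_grid,
    resample_uniform,
)


def jittered_stream(kind, func, duration, nominal_rate, jitter_s, seed=0):
    rng = np.random.default_rng(seed)
    dt = 1.0 / nominal_rate
    n = int(duration * nominal_rate)
    steps = dt + rng.uniform(-jitter_s, jitter_s, size=n)
    t = np.concatenate([[0.0], np.cumsum(steps)])
    t = t[t <= duration]
    return SensorStream(
        kind=kind, t_ns=np.round(t * 1e9).astype(np.int64), values=func(t)
    ), t


class TestSensorStream:
    def test_rejects_non_monotonic_timestamps(self):
        with pytest.raises(ValueError, match="index 2"):
            SensorStream(
                kind="accelerometer",
                t_ns=np.array([0, 10, 10, 30]),
                values=np.zeros((4, 3)),
            )

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            SensorStream(kind="gyroscope", t_ns=np.arange(3), values=np.zeros((4, 3)))

    def test_units_follow_kind(self):
        s = SensorStream(kind="magnetometer", t_ns=np.arange(4), values=np.zeros((4, 3)))
        assert s.units == "µT"


class TestResampleUniform:
    def test_idempotent_on_uniform_input(self):
        vals = np.sin(np.arange(400)[:, None] / 40.0 * [1.0, 2.0, 3.0])
        stream = make_uniform_stream("accelerometer", vals, rate=100.0)
        out = resample_uniform(stream, 100.0)
        assert len(out) == len(stream)
        assert np.allclose(out.values, vals, atol=1e-9)

    def test_linear_ramp_reproduced_through_jitter(self):
        ramp = lambda t: np.column_stack([2.0 * t + 1.0, -t, 0.5 * t])
        stream, _ = jittered_stream("accelerometer", ramp, 10.0, 200.0, 1e-3)
        out = resample_uniform(stream, 100.0)
        assert np.allclose(out.values, ramp(out.t_s), atol=1e-9)

    def test_ten_second_stream_yields_1001_samples(self):
        f = lambda t: np.zeros((len(t), 3))
        t = np.linspace(0.0, 10.0, 2001)  # ~5 ms spacing
        stream = SensorStream(
            kind="accelerometer", t_ns=np.round(t * 1e9).astype(np.int64), values=f(t)
        )
        out = resample_uniform(stream, 100.0)
        assert len(out) == 1001
        assert np.allclose(np.diff(out.t_s), 0.01, atol=1e-9)

    def test_too_few_samples_rejected(self):
        s = make_uniform_stream("gyroscope", np.zeros((3, 3)))
        with pytest.raises(ValueError):
            resample_uniform(s, 100.0)


class TestHighpassGravity:
    def test_dc_rejection(self):
        n = 4000
        vals = np.tile([0.0, 0.0, 9.81], (n, 1))
        out = highpass_gravity(make_uniform_stream("accelerometer", vals))
        core = out.values[500:-500]
        assert np.max(np.linalg.norm(core, axis=1)) < 0.01

    def test_passband_sinusoid_preserved(self):
        n = 4000
        t = np.arange(n) / 100.0
        sig = np.sin(2 * np.pi * 5.0 * t)
        vals = np.column_stack([sig, np.zeros(n), np.zeros(n)])
        out = highpass_gravity(make_uniform_stream("accelerometer", vals))
        core = slice(500, -500)
        amp = np.max(np.abs(out.values[core, 0]))
        assert abs(amp - 1.0) < 0.02

    def test_linearity(self):
        n = 4000
        rng = np.random.default_rng(7)
        x = rng.normal(size=(n, 3))
        y = rng.normal(size=(n, 3))
        f = lambda v: highpass_gravity(make_uniform_stream("accelerometer", v)).values
        assert np.allclose(f(2.5 * x + y), 2.5 * f(x) + f(y), atol=1e-9)

    def test_constant_plus_sinusoid_leaves_sinusoid(self):
        n = 4000
        t = np.arange(n) / 100.0
        sig = np.sin(2 * np.pi * 3.0 * t)
        vals = np.column_stack([sig + 5.0, np.zeros(n), np.zeros(n)])
        out = highpass_gravity(make_uniform_stream("accelerometer", vals))
        core = slice(500, -500)
        assert np.max(np.abs(out.values[core, 0] - sig[core])) < 0.02

    def test_short_stream_rejected(self):
        s = make_uniform_stream("accelerometer", np.zeros((100, 3)))
        with pytest.raises(ValueError):
            highpass_gravity(s)


def burst_stream(centers, duration=60.0, rate=100.0, amp=1.0, seed=0):
    """Quiescent noise with smooth acceleration bursts at given centers."""
    rng = np.random.default_rng(seed)
    n = int(duration * rate) + 1
    t = np.arange(n) / rate
    vals = rng.normal(scale=0.01, size=(n, 3))
    for c in centers:
        burst = amp * np.exp(-0.5 * ((t - c) / 0.4) ** 2) * np.sin(2 * np.pi * 1.0 * (t - c))
        vals[:, 0] += burst
    return make_uniform_stream("linear_acceleration", vals, rate=rate)


class TestDetectMovementWindows:
    def test_quiescent_stream_gives_empty_list(self):
        rng = np.random.default_rng(1)
        s = make_uniform_stream("linear_acceleration", rng.normal(scale=0.01, size=(6001, 3)))
        assert detect_movement_windows(s) == []

    def test_single_burst_centered_window(self):
        s = burst_stream([52.5])
        wins = detect_movement_windows(s)
        assert len(wins) == 1
        assert wins[0].width == pytest.approx(5.0, abs=1e-9)
        assert wins[0].start == pytest.approx(50.0, abs=0.2)
        assert wins[0].end == pytest.approx(55.0, abs=0.2)

    def test_two_bursts_give_two_disjoint_windows(self):
        s = burst_stream([20.0, 40.0])
        wins = detect_movement_windows(s)
        assert len(wins) == 2
        assert wins[0].end <= wins[1].start
        for w in wins:
            assert w.width == pytest.approx(5.0, abs=1e-9)

    def test_burst_near_edge_is_clipped_and_flagged(self):
        s = burst_stream([1.0], duration=40.0)
        wins = detect_movement_windows(s)
        assert len(wins) == 1
        assert wins[0].clipped
        assert wins[0].start >= 0.0

    def test_close_bursts_merge(self):
        s = burst_stream([30.0, 33.0])
        wins = detect_movement_windows(s)
        assert len(wins) == 1


class TestHoldToGrid:
    def test_holds_last_value(self):
        s = make_uniform_stream("magnetometer", np.arange(12, dtype=float).reshape(4, 3), rate=10.0)
        grid = np.array([0.0, 0.05, 0.1, 0.25, 0.31])
        out = hold_to_grid(s, grid)
        assert np.allclose(out[:, 0], [0, 0, 3, 6, 9])
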