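"""Gyro propagation and gradient-descent MARG fusion."""

import numpy as np
import pytest

from frtkit import quatmath as qm
from frtkit.fusion import (
    AhrsConfig,
    GRAVITY_REF,
    gyro_propagate,
    gyro_propagate_omega,
    madgwick_update,
    magnetic_reference,
    objective,
    objective_jacobian,
    run_ahrs,
)

from _madgwick_reference import reference_run

SQ2 = np.sqrt(0.5)


class TestGyroPropagate:
    def test_zero_rate_is_identity_step(self):
        q = qm.from_euler(10, 20, 30)
        assert np.allclose(gyro_propagate(q, np.zeros(3), 0.01), q)

    def test_single_step_arithmetic(self):
        q = gyro_propagate(qm.identity(), np.array([0, 0, 0.1]), 0.01)
        expected = np.array([1.0, 0.0, 0.0, 0.0005])
        assert np.allclose(q, expected / np.linalg.norm(expected), atol=1e-12)

    def test_many_steps_match_axis_angle_closed_form(self):
        q = qm.identity()
        for _ in range(1000):
            q = gyro_propagate(q, np.array([0, 0, np.pi / 2]), 0.001)
        expected = qm.from_axis_angle([0, 0, 1], np.pi / 2)
        assert qm.angular_distance(q, expected, degrees=False) < 1e-4 * 180

    def test_rejects_non_positive_dt(self):
        with pytest.raises(ValueError):
            gyro_propagate(qm.identity(), np.zeros(3), 0.0)

    def test_omega_matrix_form_agrees(self, rng):
        for _ in range(100):
            q = qm.normalize(rng.normal(size=4))
            w = rng.normal(size=3)
            a = gyro_propagate(q, w, 0.0025)
            b = gyro_propagate_omega(q, w, 0.0025)
            assert np.allclose(a, b, atol=1e-12)


class TestObjective:
    def test_aligned_case_is_zero(self):
        s = np.array([0.0, 0, 0, 1])
        assert np.allclose(objective(qm.identity(), GRAVITY_REF, s), 0.0)

    def test_rolled_frame_aligns_gravity_with_y(self):
        q = np.array([SQ2, SQ2, 0, 0])
        s = np.array([0.0, 0, 1, 0])
        assert np.allclose(objective(q, GRAVITY_REF, s), 0.0, atol=1e-12)

    def test_componentwise_difference(self):
        s = np.array([0.0, 1, 0, 0])
        assert np.allclose(objective(qm.identity(), GRAVITY_REF, s), [-1, 0, 1])

    def test_zero_measurement_rejected(self):
        with pytest.raises(ValueError):
            objective(qm.identity(), GRAVITY_REF, np.zeros(4))

    def test_jacobian_matches_numerical_differentiation(self, rng):
        """The gradient step differentiates the rotated reference written in
        its unit-constrained quadratic form; check the hand-derived partials
        against central differences of those polynomials."""

        def rotated_ref(qv, dv):
            w, x, y, z = qv
            d1, d2, d3 = dv
            return np.array(
                [
                    (1 - 2 * (y * y + z * z)) * d1 + 2 * (x * y + w * z) * d2 + 2 * (x * z - w * y) * d3,
                    2 * (x * y - w * z) * d1 + (1 - 2 * (x * x + z * z)) * d2 + 2 * (y * z + w * x) * d3,
                    2 * (x * z + w * y) * d1 + 2 * (y * z - w * x) * d2 + (1 - 2 * (x * x + y * y)) * d3,
                ]
            )

        eps = 1e-6
        for _ in range(50):
            q = qm.normalize(rng.normal(size=4))
            d = np.concatenate([[0.0], rng.normal(size=3)])
            d[1:] /= np.linalg.norm(d[1:])
            # for unit q the polynomial form equals the quaternion sandwich
            assert np.allclose(
                rotated_ref(q, d[1:]),
                qm.multiply(qm.multiply(qm.conjugate(q), d), q)[1:],
                atol=1e-12,
            )
            J = objective_jacobian(q, d)
            num = np.empty((3, 4))
            for k in range(4):
                dq = np.zeros(4)
                dq[k] = eps
                num[:, k] = (rotated_ref(q + dq, d[1:]) - rotated_ref(q - dq, d[1:])) / (2 * eps)
            assert np.allclose(J, num, atol=1e-6)


class TestMagneticReference:
    def test_horizontal_component_collapses_onto_one_axis(self):
        # rotated field (3, 4, 5): horizontal magnitude 5, vertical 5
        q = qm.identity()
        m = np.array([3.0, 4.0, 5.0])
        b = magnetic_reference(q, m)
        assert np.allclose(b[1] / b[3], 1.0)  # 5 / 5
        assert b[2] == 0.0 and b[0] == 0.0

    def test_identity_rotation_preserves_dip(self):
        m = np.array([0.0, 22.0, -40.0])
        b = magnetic_reference(qm.identity(), m)
        expected = np.array([0.0, 22.0, 0.0, -40.0])
        expected[1:] /= np.linalg.norm(expected[1:])
        assert np.allclose(b, expected)

    def test_east_component_always_zero(self, rng):
        for _ in range(50):
            q = qm.normalize(rng.normal(size=4))
            m = rng.normal(size=3) * 30
            b = magnetic_reference(q, m)
            assert b[2] == 0.0
            assert np.isclose(np.linalg.norm(b[1:]), 1.0)

    def test_zero_field_rejected(self):
        with pytest.raises(ValueError):
            magnetic_reference(qm.identity(), np.zeros(3))


class TestMadgwickUpdate:
    def test_static_aligned_sensor_is_fixed_point(self):
        cfg = AhrsConfig(sample_period=0.01, beta=0.5)
        q = qm.identity()
        for _ in range(100):
            q, _ = madgwick_update(q, np.zeros(3), np.array([0, 0, 9.81]), None, cfg)
        assert qm.angular_distance(q, qm.identity()) < 1e-9

    def test_zero_accel_falls_back_to_gyro_only(self):
        cfg = AhrsConfig(sample_period=0.01)
        q0 = qm.from_euler(5, 5, 5)
        q, corrected = madgwick_update(q0, np.zeros(3), np.zeros(3), None, cfg)
        assert not corrected
        assert np.allclose(q, q0)

    def test_tilt_recovered_from_wrong_initial_estimate(self):
        # static sensor rolled 30 deg; start from identity
        q_true = qm.from_euler(30, 0, 0)
        acc = qm.rotate_vector(qm.conjugate(q_true), np.array([0, 0, 9.81]))
        # normalized-gradient steps limit-cycle with amplitude ~2*beta*dt
        cfg = AhrsConfig(sample_period=0.01, beta=0.8, init_gain=None, motion_gate_rad_s=None)
        q = qm.identity()
        for _ in range(100):  # 1 s of samples
            q, _ = madgwick_update(q, np.zeros(3), acc, None, cfg)
        roll, pitch, _ = qm.to_euler(q)
        assert abs(roll - 30.0) < 2.0 and abs(pitch) < 2.0


class TestRunAhrs:
    def test_quiescent_input_stays_at_identity(self):
        n = 200
        cfg = AhrsConfig(sample_period=0.01)
        q = run_ahrs(np.zeros((n, 3)), np.tile([0, 0, 9.81], (n, 1)), None, cfg)
        assert np.allclose(q, qm.identity(), atol=1e-9)
        assert np.allclose(np.linalg.norm(q, axis=1), 1.0, atol=1e-9)

    def test_beta_zero_reduces_to_pure_gyro_integration(self, rng):
        n = 300
        omega = rng.normal(scale=0.5, size=(n, 3))
        accel = rng.normal(scale=1.0, size=(n, 3)) + [0, 0, 9.81]
        cfg = AhrsConfig(sample_period=0.01, beta=0.0)
        fused = run_ahrs(omega, accel, None, cfg)
        q = qm.identity()
        for i in range(n):
            q = gyro_propagate(q, omega[i], 0.01)
        assert np.allclose(fused[-1], q, atol=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            run_ahrs(np.zeros((5, 3)), np.zeros((6, 3)), None, AhrsConfig())

    def test_matches_reference_transcription(self, rng):
        """Dual-route check: general-Jacobian implementation vs the
        published scalar-form transcription, gravity-only and full MARG."""
        n = 1000
        dt, beta = 0.01, 0.1
        omega = rng.normal(scale=0.3, size=(n, 3))
        accel = np.tile([0.3, -0.2, 9.7], (n, 1)) + rng.normal(scale=0.05, size=(n, 3))
        mag = np.tile([5.0, 20.0, -38.0], (n, 1)) + rng.normal(scale=0.5, size=(n, 3))
        cfg = AhrsConfig(
            sample_period=dt, beta=beta, init_gain=None, motion_gate_rad_s=None
        )
        for m in (None, mag):
            cfg.use_magnetometer = m is not None
            ours = run_ahrs(omega, accel, m, cfg)
            ref = reference_run(omega, accel, m, dt, beta)
            worst = qm.angular_distance(ours, ref).max()
            assert worst < 0.5, f"max per-sample angular distance {worst} deg"
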