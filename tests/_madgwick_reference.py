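"""Independent reference implementation of the gradient-descent MARG filter.

A literal per-sample transcription of the originally published scalar-form
algorithm (expanded objective-function components and hard-coded Jacobian
entries), kept deliberately separate from the package implementation, which
assembles the same gradient from general sandwich-product Jacobians.  Used
only as a cross-check oracle in tests.

Quaternions are scalar-first (q1, q2, q3, q4) = (w, x, y, z); the Earth
z-axis carries gravity and the Earth field is (bx, 0, bz).
"""

from __future__ import annotations

import numpy as np


def _quat_mult(a, b):
    a1, a2, a3, a4 = a
    b1, b2, b3, b4 = b
    return np.array(
        [
            a1 * b1 - a2 * b2 - a3 * b3 - a4 * b4,
            a1 * b2 + a2 * b1 + a3 * b4 - a4 * b3,
            a1 * b3 - a2 * b4 + a3 * b1 + a4 * b2,
            a1 * b4 + a2 * b3 - a3 * b2 + a4 * b1,
        ]
    )


def reference_update(q, gyr, acc, mag, dt, beta):
    """One filter step; ``mag=None`` selects the IMU (gravity-only) form."""
    q1, q2, q3, q4 = q
    qdot = 0.5 * _quat_mult(q, np.array([0.0, *gyr]))

    a = np.asarray(acc, dtype=float)
    an = np.linalg.norm(a)
    if an > 0 and beta > 0:
        ax, ay, az = a / an
        f = np.array(
            [
                2.0 * (q2 * q4 - q1 * q3) - ax,
                2.0 * (q1 * q2 + q3 * q4) - ay,
                2.0 * (0.5 - q2 * q2 - q3 * q3) - az,
            ]
        )
        J = np.array(
            [
                [-2.0 * q3, 2.0 * q4, -2.0 * q1, 2.0 * q2],
                [2.0 * q2, 2.0 * q1, 2.0 * q4, 2.0 * q3],
                [0.0, -4.0 * q2, -4.0 * q3, 0.0],
            ]
        )
        grad = J.T @ f

        if mag is not None:
            m = np.asarray(mag, dtype=float)
            mn = np.linalg.norm(m)
            if mn > 0:
                mx, my, mz = m / mn
                h = _quat_mult(
                    _quat_mult(q, np.array([0.0, mx, my, mz])),
                    np.array([q1, -q2, -q3, -q4]),
                )
                bx = np.hypot(h[1], h[2])
                bz = h[3]
                fm = np.array(
                    [
                        2.0 * bx * (0.5 - q3 * q3 - q4 * q4)
                        + 2.0 * bz * (q2 * q4 - q1 * q3)
                        - mx,
                        2.0 * bx * (q2 * q3 - q1 * q4)
                        + 2.0 * bz * (q1 * q2 + q3 * q4)
                        - my,
                        2.0 * bx * (q1 * q3 + q2 * q4)
                        + 2.0 * bz * (0.5 - q2 * q2 - q3 * q3)
                        - mz,
                    ]
                )
                Jm = np.array(
                    [
                        [
                            -2.0 * bz * q3,
                            2.0 * bz * q4,
                            -4.0 * bx * q3 - 2.0 * bz * q1,
                            -4.0 * bx * q4 + 2.0 * bz * q2,
                        ],
                        [
                            -2.0 * bx * q4 + 2.0 * bz * q2,
                            2.0 * bx * q3 + 2.0 * bz * q1,
                            2.0 * bx * q2 + 2.0 * bz * q4,
                            -2.0 * bx * q1 + 2.0 * bz * q3,
                        ],
                        [
                            2.0 * bx * q3,
                            2.0 * bx * q4 - 4.0 * bz * q2,
                            2.0 * bx * q1 - 4.0 * bz * q3,
                            2.0 * bx * q2,
                        ],
                    ]
                )
                grad = grad + Jm.T @ fm

        gn = np.linalg.norm(grad)
        if gn > 1e-15:
            qdot = qdot - beta * grad / gn

    q_new = q + qdot * dt
    return q_new / np.linalg.norm(q_new)


def reference_run(gyr, acc, mag, dt, beta, q0=None):
    """Run the reference filter over sample tracks; returns (n, 4) track."""
    n = len(gyr)
    q = np.array([1.0, 0.0, 0.0, 0.0]) if q0 is None else np.asarray(q0, float)
    out = np.empty((n, 4))
    for i in range(n):
        q = reference_update(
            q, gyr[i], acc[i], None if mag is None else mag[i], dt, beta
        )
        out[i] = q
    return out
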