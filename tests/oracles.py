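"""Independent oracles used by the test suite.

These deliberately do not share code with the package's solvers: the RK4
integrator is a classical fixed-step scheme over a hand-written scalar
right-hand side, and the extinction scan is a plain linear search.
"""

from __future__ import annotations

import numpy as np


def rhs_scalar(t, y, p_at, p_ct, family, ab=None):
    """Plain-Python model right-hand side on the 5-vector (B_At, B_Ct, C, R, N)."""
    b1, b2, c, r_, n = [max(v, 0.0) for v in y]
    d_b = []
    d_c = 0.0
    d_r = 0.0
    for b, p in ((b1, p_at), (b2, p_ct)):
        monod = c / (c + p.K) if c > 0 else 0.0
        growth = p.r * b * monod
        d_c -= growth / p.Y
        if family == "model1":
            death = (p.beta + p.gamma * t) * c * b
        else:
            death = p.beta * r_ * b
            d_r -= p.alpha * b * r_
        d_b.append(growth - death)
    if family == "model2" and ab is not None:
        gen = (ab.d + ab.e * r_) * c
        d_r += gen - ab.l * r_
        if gen > 0:
            d_c -= gen / ab.m
    return np.array([d_b[0], d_b[1], d_c, d_r, 0.0])


def rk4_fixed_step(y0, t_end, dt, p_at, p_ct, family, ab=None):
    """Classical fourth-order Runge-Kutta with a fixed step; returns y(t_end)."""
    y = np.asarray(y0, dtype=float).copy()
    n_steps = int(round(t_end / dt))
    t = 0.0
    for _ in range(n_steps):
        k1 = rhs_scalar(t, y, p_at, p_ct, family, ab)
        k2 = rhs_scalar(t + dt / 2, y + dt / 2 * k1, p_at, p_ct, family, ab)
        k3 = rhs_scalar(t + dt / 2, y + dt / 2 * k2, p_at, p_ct, family, ab)
        k4 = rhs_scalar(t + dt, y + dt * k3, p_at, p_ct, family, ab)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        y = np.maximum(y, 0.0)
        t += dt
    return y


def extinction_scan(table, column, threshold):
    """First transfer whose end-of-cycle abundance is below threshold, else -1."""
    for _, row in table.iterrows():
        if row[column] < threshold:
            return int(row["transfer"])
    return -1
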