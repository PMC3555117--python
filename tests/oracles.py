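"""Independent numerical oracles used by the test suite.

These deliberately avoid the closed-form event-driven propagation used by
the package: the ODE oracle advances the linear inter-spike system with
fixed-step fourth-order Runge-Kutta (step 1e-3 ms), and the recursion
oracle is the instant-inactivation (tau_in -> 0) limit of the per-pulse
amplitude dynamics.
"""

from __future__ import annotations

import math

import numpy as np

RK4_STEP_MS = 1e-3


def _rk4_one_step_matrix(tau_in: float, tau_rec: float, tau_facil: float, h: float) -> np.ndarray:
    """Exact one-step RK4 update matrix for the linear system u' = A u with
    u = (y, z, p)."""
    A = np.array(
        [
            [-1.0 / tau_in, 0.0, 0.0],
            [1.0 / tau_in, -1.0 / tau_rec, 0.0],
            [0.0, 0.0, -1.0 / tau_facil],
        ]
    )
    hA = h * A
    R = np.eye(3)
    term = np.eye(3)
    for k in (1, 2, 3, 4):
        term = term @ hA / k
        R = R + term
    return R


def rk4_relax(y0, z0, p0, dt_ms, tau_in, tau_rec, tau_facil, step=RK4_STEP_MS):
    """Fixed-step RK4 integration of the inter-spike dynamics over dt_ms.

    The interval must be an integer number of steps.  Because the system is
    linear, n RK4 steps equal the n-th power of the one-step update matrix,
    which reproduces the stepped iteration exactly without a Python loop.
    """
    n = int(round(dt_ms / step))
    if abs(n * step - dt_ms) > 1e-9:
        raise ValueError("dt must be an integer number of RK4 steps")
    R = _rk4_one_step_matrix(tau_in, tau_rec, tau_facil, step)
    u = np.linalg.matrix_power(R, n) @ np.array([y0, z0, p0])
    return float(u[0]), float(u[1]), float(u[2])


def rk4_train_states(params, spike_times_ms, step=RK4_STEP_MS):
    """Pre-spike states (x, y, z, p) at each spike of a train, by fixed-step
    RK4 between spikes and the discrete facilitation/release update at
    spikes (p incremented before release)."""
    y, z, p = 0.0, 0.0, 0.0
    t_prev = 0.0
    states = []
    for t in spike_times_ms:
        if t > t_prev:
            y, z, p = rk4_relax(y, z, p, t - t_prev, params.tau_in, params.tau_rec, params.tau_facil, step)
        x = 1.0 - y - z
        states.append((x, y, z, p))
        p = p + params.U * (1.0 - p)
        delta = p * x
        y += delta
        t_prev = t
    return np.array(states)


def recursion_amplitudes(U, tau_rec, tau_facil, n_pulses, frequency_hz):
    """Normalized per-pulse amplitudes in the instant-inactivation limit:
    a_n = p_n x_n with x recovering as 1 - (1 - x (1 - p)) exp(-T/tau_rec)
    and p decaying with tau_facil between pulses."""
    T = 1000.0 / frequency_hz
    p, x = 0.0, 1.0
    amps = []
    for _ in range(n_pulses):
        p = p + U * (1.0 - p)
        amps.append(p * x)
        x = 1.0 - (1.0 - x * (1.0 - p)) * math.exp(-T / tau_rec)
        p = p * math.exp(-T / tau_facil)
    amps = np.asarray(amps)
    return amps / amps[0]


def stationary_recursion_fixed_point(U, tau_rec, tau_facil, frequency_hz):
    """Analytic fixed point of the instant-inactivation recursion under
    periodic drive: p* = U / (1 - (1-U) e^(-T/tau_facil)); x* from the
    depletion/recovery balance."""
    T = 1000.0 / frequency_hz
    ef = math.exp(-T / tau_facil)
    er = math.exp(-T / tau_rec)
    p_star = U / (1.0 - (1.0 - U) * ef)
    x_star = (1.0 - er) / (1.0 - (1.0 - p_star) * er)
    return p_star, x_star
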