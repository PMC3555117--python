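"""Numerical kernel for the free-running leaky integrate-and-fire membrane.

The membrane equation is integrated with the exponential-Euler scheme, which
is unconditionally stable for the conductance-based leak + synapse system:
at each step the instantaneous steady state and effective time constant are
computed from the total conductance and the voltage relaxes toward it.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def lif_exponential_euler(
    g_syn: np.ndarray,
    dt: float,
    capacitance_pf: float,
    g_leak: float,
    e_leak: float,
    e_syn: float,
    v_threshold: float,
    v_reset: float,
    t_refractory: float,
    adapt_increment: float,
    adapt_tau: float,
    e_adapt: float,
    v_out: np.ndarray,
    record_v: bool,
) -> np.ndarray:
    """Integrate the membrane over a synaptic-conductance grid.

    Returns the output spike times (ms).  During the absolute refractory
    period the membrane is held at the reset potential and synaptic input
    cannot trigger spikes.  Each spike increments a slow potassium-like
    adaptation conductance (``adapt_increment`` nS, decaying with
    ``adapt_tau`` ms toward zero) that hyperpolarizes the cell toward
    ``e_adapt`` — the reduced stand-in for the slow AHP of CA1 pyramidal
    cells.  Set ``adapt_increment`` to zero for a plain integrate-and-fire
    cell.
    """
    n = g_syn.shape[0]
    max_spikes = int(n * dt / t_refractory) + 2
    spikes = np.empty(max_spikes, dtype=np.float64)
    n_spikes = 0
    v = e_leak
    g_adapt = 0.0
    decay_adapt = math.exp(-dt / adapt_tau)
    ref_until = -1.0
    for k in range(n):
        t = k * dt
        g_adapt *= decay_adapt
        if t < ref_until:
            v = v_reset
        else:
            g_tot = g_leak + g_syn[k] + g_adapt
            v_inf = (g_leak * e_leak + g_syn[k] * e_syn + g_adapt * e_adapt) / g_tot
            tau_eff = capacitance_pf / g_tot
            v = v_inf + (v - v_inf) * math.exp(-dt / tau_eff)
            if v >= v_threshold:
                spikes[n_spikes] = t
                n_spikes += 1
                v = v_reset
                ref_until = t + t_refractory
                g_adapt += adapt_increment
        if record_v:
            v_out[k] = v
    return spikes[:n_spikes]
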