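"""Event-driven three-state resource model of short-term synaptic plasticity.

The synapse holds a conserved pool of resources split into recovered (x),
active (y) and inactive (z) fractions.  A presynaptic spike moves a fraction
``p * x`` of the pool into the active state; the active fraction inactivates
with time constant ``tau_in`` and returns to the recovered pool with time
constant ``tau_rec``.  The use-fraction ``p`` facilitates at each spike,
``p+ = p- + U * (1 - p-)`` (the increment is applied *before* release), and
relaxes back to 0 between spikes with time constant ``tau_facil``.  The
synaptic current is proportional to the active fraction, ``EPSC(t) = A y(t)``.

Between spikes the system is linear, so states are propagated with the exact
closed-form solution rather than stepped integration; no integration error
accumulates regardless of inter-spike interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "STPParams",
    "STPState",
    "initial_state",
    "relax",
    "apply_spike",
    "propagate",
    "epsc_trace",
    "train_amplitudes",
]

_CONSERVATION_TOL = 1e-9


@dataclass(frozen=True)
class STPParams:
    """Constants of the three-state resource synapse.

    Parameters
    ----------
    U : float
        Facilitation increment; equals the release probability at the first
        spike of a train (``p0``).  Must lie in (0, 1].
    tau_in : float
        Inactivation time constant of the active resource, ms.
    tau_rec : float
        Recovery time constant of the inactive resource, ms.
    tau_facil : float
        Decay time constant of the use-fraction ``p``, ms.
    A : float
        Absolute synaptic strength: the current (pA) produced by activating
        the entire resource pool at once.
    """

    U: float
    tau_in: float = 1.0
    tau_rec: float = 50.0
    tau_facil: float = 200.0
    A: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.U <= 1.0:
            raise ValueError(f"U must be in (0, 1], got {self.U}")
        for name in ("tau_in", "tau_rec", "tau_facil"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.A <= 0:
            raise ValueError("A must be positive")

    @property
    def p0(self) -> float:
        """Initial release probability (the value of ``p`` at the first spike)."""
        return self.U


@dataclass(frozen=True)
class STPState:
    """Dynamic state of one synapse at time ``t`` (ms).

    ``x``, ``y``, ``z`` are the recovered, active and inactive resource
    fractions (they sum to one); ``p`` is the current use-fraction.
    """

    x: float = 1.0
    y: float = 0.0
    z: float = 0.0
    p: float = 0.0
    t: float = 0.0


def initial_state() -> STPState:
    """Resting state: full recovered pool, no facilitation (x=1, y=z=p=0)."""
    return STPState()


def _relax_yz(y0: float, z0: float, dt: float, tau_in: float, tau_rec: float) -> tuple[float, float]:
    """Closed-form inter-spike solution for the active/inactive fractions."""
    ey = math.exp(-dt / tau_in)
    er = math.exp(-dt / tau_rec)
    y = y0 * ey
    if abs(tau_in - tau_rec) < 1e-12 * max(tau_in, tau_rec):
        # degenerate equal-time-constant limit: t * exp(-t/tau) particular term
        z = z0 * er + y0 * (dt / tau_rec) * er
    else:
        z = z0 * er + y0 * tau_rec / (tau_in - tau_rec) * (ey - er)
    return y, z


def relax(state: STPState, dt: float, params: STPParams) -> STPState:
    """Propagate the state across a spike-free interval of length ``dt`` ms.

    Uses the exact solution of the linear inter-spike system: ``y`` decays
    with ``tau_in``, ``z`` follows the two-exponential inactivation/recovery
    balance, ``x = 1 - y - z`` and ``p`` decays to baseline 0 with
    ``tau_facil``.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0:
        return state
    y, z = _relax_yz(state.y, state.z, dt, params.tau_in, params.tau_rec)
    p = state.p * math.exp(-dt / params.tau_facil)
    return STPState(x=1.0 - y - z, y=y, z=z, p=p, t=state.t + dt)


def apply_spike(state: STPState, params: STPParams) -> tuple[STPState, float]:
    """Apply a presynaptic spike to a state already relaxed to the spike time.

    The use-fraction is facilitated first, ``p+ = p- + U (1 - p-)``, and the
    released fraction ``delta = p+ * x-`` is then moved from the recovered to
    the active pool.  Returns the post-spike state and ``delta``.
    """
    p_plus = state.p + params.U * (1.0 - state.p)
    delta = p_plus * state.x
    new = STPState(x=state.x - delta, y=state.y + delta, z=state.z, p=p_plus, t=state.t)
    return new, delta


def _check_spike_times(spike_times_ms: np.ndarray) -> np.ndarray:
    times = np.asarray(spike_times_ms, dtype=float)
    if times.ndim != 1:
        raise ValueError("spike times must be one-dimensional")
    if times.size and (np.any(np.diff(times) <= 0)):
        raise ValueError("spike times must be strictly increasing (no duplicates)")
    if times.size and times[0] < 0:
        raise ValueError("spike times must be non-negative")
    return times


def propagate(params: STPParams, spike_times_ms) -> dict[str, np.ndarray]:
    """Evolve the synapse through a spike train, event by event.

    Returns per-spike arrays: the pre-spike state (``x_pre``, ``y_pre``,
    ``z_pre``, ``p_pre``), the post-spike values (``y_post``, ``p_post``)
    and the released fraction ``released``.  This is the engine behind both
    the EPSC traces and the per-pulse amplitudes.
    """
    times = _check_spike_times(spike_times_ms)
    n = times.size
    out = {k: np.empty(n) for k in ("x_pre", "y_pre", "z_pre", "p_pre", "y_post", "p_post", "released")}
    state = initial_state()
    for i, t in enumerate(times):
        state = relax(state, t - state.t, params)
        out["x_pre"][i] = state.x
        out["y_pre"][i] = state.y
        out["z_pre"][i] = state.z
        out["p_pre"][i] = state.p
        state, delta = apply_spike(state, params)
        out["y_post"][i] = state.y
        out["p_post"][i] = state.p
        out["released"][i] = delta
    return out


def active_fraction_on_grid(params: STPParams, spike_times_ms, t_grid_ms: np.ndarray) -> np.ndarray:
    """Evaluate y(t) on an arbitrary time grid by closed-form decay from the
    most recent spike (zero before the first spike)."""
    times = _check_spike_times(spike_times_ms)
    y = np.zeros_like(np.asarray(t_grid_ms, dtype=float))
    if times.size == 0:
        return y
    states = propagate(params, times)
    idx = np.searchsorted(times, t_grid_ms, side="right") - 1
    mask = idx >= 0
    if np.any(mask):
        last = idx[mask]
        y[mask] = states["y_post"][last] * np.exp(-(t_grid_ms[mask] - times[last]) / params.tau_in)
    return y


def epsc_trace(
    params: STPParams,
    spike_times_ms,
    sample_step: float,
    duration_ms: float | None = None,
    inward_negative: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the synaptic current ``EPSC(t) = A y(t)`` on a regular grid.

    The trace is exact at every sample: between spikes ``y`` follows its
    closed-form exponential decay, and at each spike it jumps upward by the
    released fraction.  By default the magnitude is reported positive; set
    ``inward_negative`` for the inward-current display convention.

    Returns ``(t_ms, current_pA)``.
    """
    if sample_step <= 0:
        raise ValueError("sample_step must be positive")
    times = _check_spike_times(spike_times_ms)
    if duration_ms is None:
        tail = 5.0 * max(params.tau_in, 1.0)
        duration_ms = (times[-1] + tail) if times.size else 10.0 * sample_step
    t_grid = np.arange(0.0, duration_ms + 0.5 * sample_step, sample_step)
    current = params.A * active_fraction_on_grid(params, times, t_grid)
    if inward_negative:
        current = -current
    return t_grid, current


def train_amplitudes(params: STPParams, n_pulses: int, frequency_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-pulse peak EPSC amplitudes for a regular train.

    The amplitude of pulse ``i`` is the maximum of ``A y(t)`` attributable
    to that pulse.  Because ``y`` decays monotonically between spikes, the
    maximum sits at the spike time itself and equals ``A * y_post``; residual
    active resource from earlier pulses is included (no baseline
    subtraction).

    Returns ``(amplitudes_pA, normalized)`` with ``normalized[0] == 1``.
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be at least 1")
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    period = 1000.0 / frequency_hz
    times = np.arange(n_pulses) * period
    states = propagate(params, times)
    amps = params.A * states["y_post"]
    return amps, amps / amps[0]
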