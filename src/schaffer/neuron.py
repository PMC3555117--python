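"""Reduced CA1 surrogate neuron: a conductance-based leaky integrate-and-fire
cell with voltage-clamp and free-running modes.

The cell replaces a morphologically detailed CA1 pyramidal model with a
single compartment.  In clamp mode the somatic current is the weighted sum of
the per-synapse active resource times the driving force (no spiking); in free
mode the membrane integrates the synaptic conductances, fires on threshold
crossing, resets and honours an absolute refractory period.  Synaptic state
is always advanced with the event-driven closed form of the plasticity model
and only sampled onto the voltage grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import lif_exponential_euler
from .drive import SynapsePopulation, as_rng
from .spiketrain import SpikeTrain
from .stp import active_fraction_on_grid

__all__ = [
    "NeuronParams",
    "CalibrationError",
    "RegimeCalibration",
    "run_voltage_clamp",
    "run_free",
    "calibrate_regimes",
    "synaptic_conductance",
]


@dataclass(frozen=True)
class NeuronParams:
    """Electrical parameters of the reduced CA1 cell.

    Defaults: 20 ms membrane time constant with a 10 nS leak (200 pF),
    resting at -70 mV, threshold -54 mV, reset -65 mV, 3 ms absolute
    refractory period, excitatory synaptic reversal at 0 mV.  The clamp
    potential realizes the -70 mV somatic voltage clamp of the recording
    protocols.

    Each output spike also increments a slow potassium-like adaptation
    conductance (reversal ``adaptation_reversal``) that decays with
    ``adaptation_tau``; this is the single-compartment stand-in for the
    slow after-hyperpolarization of CA1 pyramidal cells, which spaces
    output spikes and makes strongly driven cells accumulate
    self-inhibition.  Set ``adaptation_increment = 0`` for a plain
    integrate-and-fire cell.
    """

    membrane_time_constant: float = 20.0
    leak_conductance: float = 10.0
    resting_potential: float = -70.0
    spike_threshold: float = -54.0
    reset_potential: float = -65.0
    refractory_period: float = 3.0
    synaptic_reversal: float = 0.0
    clamp_potential: float = -70.0
    adaptation_increment: float = 32.0
    adaptation_tau: float = 300.0
    adaptation_reversal: float = -90.0

    def __post_init__(self) -> None:
        if self.refractory_period <= 0:
            raise ValueError("refractory_period must be positive")
        if self.spike_threshold <= self.reset_potential:
            raise ValueError("spike_threshold must exceed reset_potential")
        if self.synaptic_reversal <= self.spike_threshold:
            raise ValueError("synaptic_reversal must exceed spike_threshold")
        if self.adaptation_increment < 0 or self.adaptation_tau <= 0:
            raise ValueError("adaptation increment must be >= 0 and tau positive")

    @property
    def capacitance_pf(self) -> float:
        return self.membrane_time_constant * self.leak_conductance


class CalibrationError(RuntimeError):
    """Raised when no weight scale can reach the requested probability band."""


def synaptic_conductance(
    population: SynapsePopulation,
    input_events_ms: list[np.ndarray],
    t_grid_ms: np.ndarray,
) -> np.ndarray:
    """Total synaptic conductance (nS) on a time grid.

    Each synapse's active fraction is propagated event-by-event in closed
    form and evaluated on the grid; contributions sum linearly with the
    effective (attenuated) weights.
    """
    if population.n != len(input_events_ms):
        raise ValueError("one event train per synapse is required")
    eff = population.effective_weights_ns
    first = np.asarray(input_events_ms[0], dtype=float)
    synchronous = all(
        len(ev) == len(first) and np.array_equal(np.asarray(ev, dtype=float), first)
        for ev in input_events_ms[1:]
    )
    if synchronous:
        # identical kinetics and drive: one propagation scaled by total weight
        return float(np.sum(eff)) * active_fraction_on_grid(population.params, first, t_grid_ms)
    g = np.zeros_like(t_grid_ms)
    for w, events in zip(eff, input_events_ms):
        g += w * active_fraction_on_grid(population.params, events, t_grid_ms)
    return g


def run_voltage_clamp(
    population: SynapsePopulation,
    input_events_ms: list[np.ndarray],
    hold_mv: float = -70.0,
    sample_step: float = 0.1,
    duration_ms: float | None = None,
    reversal_mv: float = 0.0,
    inward_negative: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Total clamp current (pA) with the soma held at ``hold_mv``.

    The current is the sum over synapses of weight * y_i(t) * driving force;
    no spiking occurs in clamp mode.  Returns ``(t_ms, current_pA)`` with the
    magnitude positive unless ``inward_negative`` is set.
    """
    if population.n < 1:
        raise ValueError("population must not be empty")
    if sample_step <= 0:
        raise ValueError("sample_step must be positive")
    if duration_ms is None:
        last = max((ev[-1] for ev in input_events_ms if len(ev)), default=0.0)
        duration_ms = last + 5.0 * max(population.params.tau_in, 1.0)
    t_grid = np.arange(0.0, duration_ms + 0.5 * sample_step, sample_step)
    g = synaptic_conductance(population, input_events_ms, t_grid)
    current = g * abs(hold_mv - reversal_mv)
    if inward_negative:
        current = -current
    return t_grid, current


def run_free(
    population: SynapsePopulation,
    input_events_ms: list[np.ndarray],
    params: NeuronParams = NeuronParams(),
    sample_step: float = 0.025,
    duration_ms: float | None = None,
    record_voltage: bool = False,
) -> tuple[SpikeTrain, np.ndarray | None]:
    """Free-running simulation: integrate the membrane and emit spikes.

    Returns the output spike train and, when requested, the membrane trace
    on the sampling grid.  ``sample_step`` must not exceed one tenth of the
    membrane time constant.
    """
    if population.n < 1:
        raise ValueError("population must not be empty")
    if sample_step > 0.1 * params.membrane_time_constant:
        raise ValueError("sample_step too large for stable integration (> 0.1 * membrane time constant)")
    if duration_ms is None:
        last = max((ev[-1] for ev in input_events_ms if len(ev)), default=0.0)
        duration_ms = last + 5.0 * params.membrane_time_constant
    t_grid = np.arange(0.0, duration_ms, sample_step)
    g = synaptic_conductance(population, input_events_ms, t_grid)
    v_out = np.empty(t_grid.size) if record_voltage else np.empty(0)
    spikes = lif_exponential_euler(
        g,
        sample_step,
        params.capacitance_pf,
        params.leak_conductance,
        params.resting_potential,
        params.synaptic_reversal,
        params.spike_threshold,
        params.reset_potential,
        params.refractory_period,
        params.adaptation_increment,
        params.adaptation_tau,
        params.adaptation_reversal,
        v_out,
        record_voltage,
    )
    train = SpikeTrain(times_ms=spikes, duration_ms=duration_ms)
    return train, (v_out if record_voltage else None)


@dataclass(frozen=True)
class RegimeCalibration:
    """Weight scale factors realizing two spike-probability regimes."""

    integrative_scale: float
    saturating_scale: float
    integrative_probability: float
    saturating_probability: float


def _mean_spike_probability(
    population_factory,
    drives: list[SpikeTrain],
    scale: float,
    params: NeuronParams,
    n_trials: int,
    master_seed: int,
    sample_step: float,
) -> float:
    """Mean output-spike probability (%) over trials cycling the drive set.

    Trial seeds derive from ``master_seed`` so repeated evaluations at
    different scales share randomness (monotone, bisect-friendly).
    """
    seeds = np.random.SeedSequence(master_seed).spawn(n_trials)
    probs = []
    for i in range(n_trials):
        rng = np.random.default_rng(seeds[i])
        drive = drives[i % len(drives)]
        pop = population_factory(rng).scaled(scale)
        events = [drive.times_ms.copy() for _ in range(pop.n)]
        out, _ = run_free(pop, events, params, sample_step=sample_step, duration_ms=drive.duration_ms)
        probs.append(100.0 * out.n / drive.n)
    return float(np.mean(probs))


def calibrate_regimes(
    population_factory,
    drives: list[SpikeTrain],
    bands: tuple[tuple[float, float], tuple[float, float]] = ((25.0, 40.0), (85.0, 92.0)),
    params: NeuronParams = NeuronParams(),
    n_trials: int = 10,
    master_seed: int = 0,
    sample_step: float = 0.025,
    max_iter: int = 30,
    max_scale: float = 200.0,
) -> RegimeCalibration:
    """Find weight multipliers whose mean spike probability enters two bands.

    ``population_factory(rng)`` must build a fresh population (weights and
    attenuations resampled) per trial.  For each target band a bisection on
    a uniform weight multiplier runs until the 10-trial mean probability
    falls inside the band.  Raises :class:`CalibrationError` when a band is
    unreachable (e.g. above the refractory ceiling).
    """
    if not drives:
        raise ValueError("drive set must not be empty")
    lo_band, hi_band = sorted(bands, key=lambda b: b[0])

    def sp(scale: float) -> float:
        return _mean_spike_probability(population_factory, drives, scale, params, n_trials, master_seed, sample_step)

    # shared bracket: grow the upper scale until it exceeds the higher band
    hi_scale = 1.0
    hi_val = sp(hi_scale)
    grow = 0
    while hi_val < hi_band[0] and hi_scale < max_scale:
        hi_scale *= 2.0
        hi_val = sp(hi_scale)
        grow += 1
    if hi_val < hi_band[0]:
        raise CalibrationError(
            f"saturating band {hi_band} unreachable: probability {hi_val:.1f}% at scale {hi_scale:g} "
            "(refractory ceiling or insufficient drive)"
        )

    results = []
    for band in (lo_band, hi_band):
        lo, hi = 0.0, hi_scale
        val_hi = hi_val
        if val_hi < band[0]:
            raise CalibrationError(f"band {band} unreachable (max probability {val_hi:.1f}%)")
        achieved = None
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            v = sp(mid)
            if band[0] <= v <= band[1]:
                achieved = (mid, v)
                break
            if v < band[0]:
                lo = mid
            else:
                hi = mid
        if achieved is None:
            raise CalibrationError(f"bisection failed to enter band {band} within {max_iter} iterations")
        results.append(achieved)
    return RegimeCalibration(
        integrative_scale=results[0][0],
        saturating_scale=results[1][0],
        integrative_probability=results[0][1],
        saturating_probability=results[1][1],
    )
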