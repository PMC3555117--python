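"""Synthetic naturalistic CA3 pyramidal-cell spike trains.

Emulates 10-minute open-field recordings of CA3 place cells with a
doubly-stochastic, theta-modulated inhomogeneous Poisson process: a tonic
out-of-field baseline rate, brief high-rate Gaussian envelopes standing in
for the complex-spike burst events emitted during place-field traversals
(instantaneous rates reaching ~100 Hz, the hallmark of CA3 pyramidal cells
in vivo), multiplicative theta (8 Hz) modulation, and a short presynaptic
refractory period enforced by thinning.  Default parameters produce
irregular bursty trains with an ISI coefficient of variation around 1.25,
the irregularity of the recordings they stand in for, with inter-spike
intervals populating both the theta (4-8 Hz) and gamma (40-80 Hz) bands.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .drive import as_rng
from .spikestats import isi_cv
from .spiketrain import SpikeTrain, read_spike_file, write_spike_file

__all__ = [
    "CA3PatternParams",
    "generate_pattern",
    "rate_profile",
    "summarize",
    "load_fixture_patterns",
    "FIXTURE_SEEDS",
]

#: Seeds of the five shipped fixture patterns (stand-ins for cells c1-c5).
FIXTURE_SEEDS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class CA3PatternParams:
    """Parameters of the synthetic CA3 spike-train generator.

    ``field_event_rate_per_min`` is the Poisson rate of place-field burst
    events; each contributes a Gaussian rate envelope of standard deviation
    ``field_width_s`` and peak ``field_peak_rate_hz`` (default: ~100 ms
    packets peaking at 100 Hz, i.e. complex-spike bursts of roughly 4-8
    action potentials).  The total rate is multiplied by
    ``1 + theta_depth * sin(2 pi f t)``.  ``min_isi_ms`` imposes
    presynaptic refractoriness by thinning.
    """

    duration_s: float = 600.0
    baseline_rate_hz: float = 2.5
    field_event_rate_per_min: float = 6.0
    field_peak_rate_hz: float = 100.0
    field_width_s: float = 0.04
    theta_frequency_hz: float = 8.0
    theta_depth: float = 0.6
    min_isi_ms: float = 3.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        for name in ("baseline_rate_hz", "field_event_rate_per_min", "field_peak_rate_hz", "min_isi_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.theta_depth <= 1.0:
            raise ValueError("theta_depth must lie in [0, 1]")


def _field_envelope(t, centers: np.ndarray, params: CA3PatternParams) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    env = np.zeros_like(t)
    w2 = 2.0 * params.field_width_s**2
    for c in centers:
        env += params.field_peak_rate_hz * np.exp(-((t - c) ** 2) / w2)
    return env


def rate_profile(params: CA3PatternParams, field_centers, t) -> np.ndarray:
    """Instantaneous rate lambda(t), Hz, for given field-traversal centers."""
    base = params.baseline_rate_hz + _field_envelope(t, np.asarray(field_centers, dtype=float), params)
    theta = 1.0 + params.theta_depth * np.sin(2.0 * np.pi * params.theta_frequency_hz * np.asarray(t, dtype=float))
    return base * theta


def generate_pattern(params: CA3PatternParams = CA3PatternParams(), seed=None) -> SpikeTrain:
    """Draw one synthetic CA3 spike train (deterministic under ``seed``).

    Field-traversal times are Poisson; spikes are then drawn from the
    inhomogeneous Poisson rate by thinning against an upper bound computed
    on a fine grid, and finally thinned again to enforce ``min_isi_ms``.
    """
    rng = as_rng(seed)
    n_fields = rng.poisson(params.field_event_rate_per_min * params.duration_s / 60.0)
    centers = np.sort(rng.uniform(0.0, params.duration_s, size=n_fields))

    # Upper bound for thinning: grid max of the envelope (the rate varies on
    # the field-width scale, ~1 s, so a 1 ms grid with 5% headroom bounds it)
    grid = np.arange(0.0, params.duration_s, 1e-3)
    env_max = params.baseline_rate_hz + (_field_envelope(grid, centers, params).max() if grid.size else 0.0)
    lam_max = 1.05 * env_max * (1.0 + params.theta_depth)
    if lam_max <= 0:
        return SpikeTrain.from_seconds(np.array([]), params.duration_s)

    n_cand = rng.poisson(lam_max * params.duration_s)
    cand = np.sort(rng.uniform(0.0, params.duration_s, size=n_cand))
    accept = rng.uniform(0.0, 1.0, size=n_cand) * lam_max < rate_profile(params, centers, cand)
    times = cand[accept]

    if params.min_isi_ms > 0 and times.size:
        min_isi = params.min_isi_ms / 1000.0
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= min_isi:
                kept.append(t)
        times = np.asarray(kept)
    return SpikeTrain.from_seconds(times, params.duration_s)


def summarize(train: SpikeTrain) -> dict[str, float]:
    """Event count, mean rate (Hz) and ISI CV of a spike train."""
    return {
        "n_events": train.n,
        "mean_rate_hz": train.n / train.duration_s,
        "isi_cv": isi_cv(train),
    }


def load_fixture_patterns() -> list[SpikeTrain]:
    """Load the five shipped 10-minute fixture patterns (synthetic stand-ins
    for the five recorded CA3 neurons, generated from seeds 1-5)."""
    trains = []
    base = resources.files("schaffer").joinpath("data/patterns")
    for seed in FIXTURE_SEEDS:
        with resources.as_file(base.joinpath(f"c{seed}.txt")) as path:
            trains.append(read_spike_file(path, duration_s=600.0))
    return trains
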