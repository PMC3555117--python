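"""Synapse populations and stimulation protocols.

A CA1 apical-trunk input is modelled as a population of (by default) ten
synapses, each standing in for ~15 real contacts.  Peak conductances are
derived from miniature-EPSC amplitudes drawn from a shifted lognormal
distribution, and the afferent spike pattern can be delivered to all
synapses synchronously or with per-event uniform jitter (asynchronous
activation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stp import STPParams

__all__ = [
    "WeightDistribution",
    "SynapsePopulation",
    "sample_weights",
    "amplitude_to_weight",
    "jitter_events",
    "constant_train",
    "build_population",
]


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, Generator, or None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class WeightDistribution:
    """Shifted lognormal distribution of mEPSC amplitudes (pA).

    Draws are ``shift + LogNormal(mu, sigma)``: ``mu`` is the log-scale
    parameter, ``sigma`` the shape, and ``shift`` the location offset x0.
    Defaults correspond to the mEPSC amplitude fit used to seed the model
    (mu=1.6, sigma=1, x0=5 pA).
    """

    mu: float = 1.6
    sigma: float = 1.0
    shift: float = 5.0
    clamp_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.shift < 0:
            raise ValueError("shift must be non-negative")

    def cdf(self, x) -> np.ndarray:
        """Analytic CDF of the shifted lognormal (for distribution checks)."""
        from scipy import stats

        return stats.lognorm.cdf(np.asarray(x) - self.shift, s=self.sigma, scale=np.exp(self.mu))


def sample_weights(n: int, dist: WeightDistribution = WeightDistribution(), rng=None) -> np.ndarray:
    """Draw ``n`` mEPSC amplitudes (pA) from the shifted lognormal."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = as_rng(rng)
    amps = dist.shift + rng.lognormal(dist.mu, dist.sigma, size=n)
    if dist.clamp_bounds is not None:
        amps = np.clip(amps, *dist.clamp_bounds)
    return amps


def amplitude_to_weight(
    amplitude_pa: float,
    hold_mv: float = -70.0,
    reversal_mv: float = 0.0,
    multiplicity: int = 15,
) -> float:
    """Convert an mEPSC amplitude to a model peak conductance (nS).

    One model synapse aggregates ``multiplicity`` real synapses, so the
    conductance is ``multiplicity * amplitude / |hold - reversal|``.
    """
    driving = hold_mv - reversal_mv
    if driving == 0:
        raise ValueError("zero driving force: hold equals reversal")
    return multiplicity * amplitude_pa / abs(driving)


def constant_train(frequency_hz: float, n_pulses: int, start_ms: float = 0.0) -> np.ndarray:
    """Regular stimulation train: ``n_pulses`` events spaced 1000/f ms apart."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    if n_pulses < 1:
        raise ValueError("n_pulses must be at least 1")
    return start_ms + np.arange(n_pulses) * (1000.0 / frequency_hz)


def jitter_events(
    times_ms,
    jitter_range_ms: tuple[float, float] = (0.0, 9.0),
    n_synapses: int = 10,
    rng=None,
    per_event: bool = True,
) -> list[np.ndarray]:
    """Deliver one afferent pattern to ``n_synapses`` synapses with jitter.

    Each synapse receives a copy of the pattern offset by independent uniform
    draws from ``jitter_range_ms``; with ``per_event=True`` (the stronger
    desynchronization) every event gets its own offset, otherwise one offset
    is drawn per synapse.  A zero-width range reproduces synchronous
    activation exactly.  Outputs are sorted per synapse.
    """
    lo, hi = jitter_range_ms
    if lo < 0 or hi < lo:
        raise ValueError("jitter range must satisfy 0 <= lo <= hi")
    times = np.asarray(times_ms, dtype=float)
    rng = as_rng(rng)
    out = []
    for _ in range(n_synapses):
        if hi == lo:
            offs = lo
        elif per_event:
            offs = rng.uniform(lo, hi, size=times.size)
        else:
            offs = rng.uniform(lo, hi)
        out.append(np.sort(times + offs))
    return out


@dataclass(frozen=True)
class SynapsePopulation:
    """A set of synapses with shared kinetics and individual weights.

    ``weights_ns`` are peak conductances (nS, multiplicity already folded
    in); ``attenuations`` are per-synapse dendritic attenuation factors
    standing in for electrotonic distance along the apical trunk.
    """

    params: STPParams
    weights_ns: np.ndarray
    attenuations: np.ndarray
    multiplicity: int = 15

    def __post_init__(self) -> None:
        w = np.asarray(self.weights_ns, dtype=float)
        a = np.asarray(self.attenuations, dtype=float)
        object.__setattr__(self, "weights_ns", w)
        object.__setattr__(self, "attenuations", a)
        if w.size < 1:
            raise ValueError("population must contain at least one synapse")
        if w.size != a.size:
            raise ValueError("weights and attenuations must have equal length")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")

    @property
    def n(self) -> int:
        return int(self.weights_ns.size)

    @property
    def effective_weights_ns(self) -> np.ndarray:
        return self.weights_ns * self.attenuations

    def scaled(self, factor: float) -> "SynapsePopulation":
        return SynapsePopulation(self.params, self.weights_ns * factor, self.attenuations, self.multiplicity)


def build_population(
    params: STPParams,
    n: int = 10,
    dist: WeightDistribution = WeightDistribution(),
    multiplicity: int = 15,
    hold_mv: float = -70.0,
    reversal_mv: float = 0.0,
    attenuation_range: tuple[float, float] | None = (0.7, 1.0),
    rng=None,
) -> SynapsePopulation:
    """Sample a synapse population: lognormal mEPSC amplitudes converted to
    conductances, with optional uniform dendritic attenuation factors."""
    rng = as_rng(rng)
    amps = sample_weights(n, dist, rng)
    weights = np.array([amplitude_to_weight(a, hold_mv, reversal_mv, multiplicity) for a in amps])
    if attenuation_range is None:
        atten = np.ones(n)
    else:
        atten = rng.uniform(attenuation_range[0], attenuation_range[1], size=n)
    return SynapsePopulation(params=params, weights_ns=weights, attenuations=atten, multiplicity=multiplicity)
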