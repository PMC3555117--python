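"""Spike-train statistics and the statistical comparisons used downstream.

Covers spike probability (output spikes per stimulus), ISI coefficient of
variation, instantaneous-frequency histograms and band probabilities
(theta 4-8 Hz, gamma 40-80 Hz), plus paired-mean / distribution / normality
tests for condition contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spiketrain import SpikeTrain

__all__ = [
    "THETA_BAND",
    "GAMMA_BAND",
    "FrequencyHistogram",
    "TestReport",
    "spike_probability",
    "isi_cv",
    "instantaneous_frequency",
    "band_probability",
    "compare_conditions",
    "mean_sem",
]

THETA_BAND = (4.0, 8.0)
GAMMA_BAND = (40.0, 80.0)

SIGNIFICANCE_LEVEL = 0.05


class UndefinedStatisticError(ValueError):
    """Raised when a train has too few events for the requested statistic."""


@dataclass(frozen=True)
class FrequencyHistogram:
    """Instantaneous-frequency histogram normalized to event probabilities."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    n_events: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probabilities", probs)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")


@dataclass(frozen=True)
class TestReport:
    """Outcome of a statistical comparison (alpha = 0.05)."""

    kind: str
    statistic: float
    p_value: float
    significant: bool
    warning: str | None = None


def spike_probability(n_output_spikes: int, n_stimuli: int) -> float:
    """Spike probability as a percentage: 100 * output spikes / stimuli.

    Values above 100% (neuron emitting more spikes than stimuli) are allowed
    but flagged with a warning.
    """
    if n_stimuli <= 0:
        raise ValueError("n_stimuli must be positive")
    pct = 100.0 * n_output_spikes / n_stimuli
    if pct > 100.0:
        warnings.warn("spike probability exceeds 100%: more output spikes than stimuli")
    return pct


def _isis_s(train: SpikeTrain) -> np.ndarray:
    return np.diff(train.times_s)


def isi_cv(train: SpikeTrain) -> float:
    """Coefficient of variation of the inter-spike intervals (population std).

    Requires at least three events (two intervals).
    """
    if train.n < 3:
        raise UndefinedStatisticError("ISI CV requires at least 3 events")
    isis = _isis_s(train)
    return float(np.std(isis) / np.mean(isis))


def instantaneous_frequency(train: SpikeTrain, bins) -> FrequencyHistogram:
    """Histogram of instantaneous frequencies (1/ISI, Hz) as probabilities.

    Probabilities are normalized by the total ISI count, so they sum to one
    when the bins cover the observed range and to less otherwise.
    """
    if train.n < 2:
        raise UndefinedStatisticError("instantaneous frequency requires at least 2 spikes")
    freqs = 1.0 / _isis_s(train)
    edges = np.asarray(bins, dtype=float)
    counts, edges = np.histogram(freqs, bins=edges)
    return FrequencyHistogram(bin_edges=edges, probabilities=counts / freqs.size, n_events=int(freqs.size))


def band_probability(train: SpikeTrain, band: tuple[float, float]) -> float:
    """Fraction of ISIs whose instantaneous frequency falls in ``band``
    (closed interval on both edges)."""
    if train.n < 2:
        raise UndefinedStatisticError("band probability requires at least 2 spikes")
    freqs = 1.0 / _isis_s(train)
    lo, hi = band
    return float(np.mean((freqs >= lo) & (freqs <= hi)))


def compare_conditions(values_a, values_b, kind: str = "paired-mean") -> TestReport:
    """Compare two condition samples.

    ``paired-mean`` runs a paired t-test (gated by a Shapiro-Wilk normality
    check on the differences: violation adds a warning, the test still
    runs); ``distribution`` runs a two-sample Kolmogorov-Smirnov test;
    ``normality`` runs Shapiro-Wilk on ``values_a`` alone.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float) if values_b is not None else None

    if kind == "normality":
        if a.size < 3:
            raise ValueError("normality test requires n >= 3")
        stat, p = stats.shapiro(a)
        return TestReport("normality", float(stat), float(p), bool(p < SIGNIFICANCE_LEVEL))

    if b is None:
        raise ValueError("two samples required")
    if kind == "paired-mean":
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        if a.size < 3:
            raise ValueError("paired test requires n >= 3")
        diffs = a - b
        warning = None
        if np.ptp(diffs) == 0:
            # identical pairs: t statistic degenerates to 0/0; report p = 1
            return TestReport("paired-mean", 0.0, 1.0, False, "zero-variance differences")
        _, p_norm = stats.shapiro(diffs)
        if p_norm < SIGNIFICANCE_LEVEL:
            warning = f"differences fail Shapiro-Wilk normality (p={p_norm:.3g})"
        stat, p = stats.ttest_rel(a, b)
        return TestReport("paired-mean", float(stat), float(p), bool(p < SIGNIFICANCE_LEVEL), warning)
    if kind == "distribution":
        if a.size < 3 or b.size < 3:
            raise ValueError("distribution test requires n >= 3 per sample")
        stat, p = stats.ks_2samp(a, b)
        return TestReport("distribution", float(stat), float(p), bool(p < SIGNIFICANCE_LEVEL))
    raise ValueError(f"unknown comparison kind: {kind}")


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float(v.mean()), float("nan")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))
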