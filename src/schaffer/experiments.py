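"""End-to-end computational experiments with seeded reproducibility.

Four protocols mirror the study design:

* ``run_validation`` — five-pulse 100 Hz voltage-clamp trains, control
  (U = 0.15) vs increased-amyloid-beta (U = 0.36) conditions.
* ``run_frequency_sweep`` — ten-pulse clamp trains from 5 to 200 Hz.
* ``run_weight_sweep`` — free-running drive with naturalistic patterns over
  a range of uniform weight multipliers, with sigmoid fits of spike
  probability vs mean peak conductance, synchronous and asynchronous
  (0-9 ms jitter) activation.
* ``run_natural_drive`` — the five naturalistic patterns in integrative and
  saturating regimes, with spike probability, ISI CV, frequency-band
  statistics and the paired condition comparisons.

Trial seeds derive deterministically from the master seed via
``numpy.random.SeedSequence(master_seed).spawn``; the same per-trial seed is
used for both conditions, so weights, attenuations and jitter are matched
pairs and identical configurations rerun byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import spikestats
from .drive import SynapsePopulation, WeightDistribution, build_population, jitter_events
from .fitting import SigmoidFit, fit_sigmoid
from .neuron import NeuronParams, RegimeCalibration, run_free
from .patterns import CA3PatternParams, FIXTURE_SEEDS, generate_pattern
from .spiketrain import SpikeTrain
from .stp import STPParams, train_amplitudes

__all__ = [
    "CONDITIONS",
    "condition_params",
    "PopulationSpec",
    "ExperimentConfig",
    "ExperimentResult",
    "run_validation",
    "run_frequency_sweep",
    "run_weight_sweep",
    "run_natural_drive",
    "default_drives",
]

#: Named synapse parameter sets (time constants shared; only the initial
#: release probability differs between conditions).
CONDITIONS: dict[str, dict[str, float]] = {
    "control": {"U": 0.15, "tau_in": 1.0, "tau_rec": 50.0, "tau_facil": 200.0},
    "abeta": {"U": 0.36, "tau_in": 1.0, "tau_rec": 50.0, "tau_facil": 200.0},
}


def condition_params(condition: str, A: float = 1.0, custom: dict | None = None) -> STPParams:
    """Resolve a named condition (or ``custom`` parameter dict) to STPParams."""
    if condition == "custom":
        if not custom:
            raise ValueError("custom condition requires a parameter dict")
        return STPParams(A=A, **custom)
    try:
        return STPParams(A=A, **CONDITIONS[condition])
    except KeyError:
        raise ValueError(f"unknown condition {condition!r}; expected control, abeta or custom") from None


@dataclass(frozen=True)
class PopulationSpec:
    """How synapse populations are sampled each trial."""

    n_synapses: int = 10
    multiplicity: int = 15
    distribution: WeightDistribution = field(default_factory=WeightDistribution)
    attenuation_range: tuple[float, float] | None = (0.7, 1.0)
    jitter_range_ms: tuple[float, float] = (0.0, 9.0)
    hold_mv: float = -70.0
    reversal_mv: float = 0.0

    def build(self, params: STPParams, rng) -> SynapsePopulation:
        return build_population(
            params,
            n=self.n_synapses,
            dist=self.distribution,
            multiplicity=self.multiplicity,
            hold_mv=self.hold_mv,
            reversal_mv=self.reversal_mv,
            attenuation_range=self.attenuation_range,
            rng=rng,
        )


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared configuration for the experiment runners.

    The synthetic drive defaults to 60 s patterns (a tenth of the 10-minute
    recordings they emulate) so full experiment suites run at desk scale;
    set ``pattern.duration_s = 600`` for full-length drive.
    """

    conditions: tuple[str, ...] = ("control", "abeta")
    custom_stp: dict | None = None
    population: PopulationSpec = field(default_factory=PopulationSpec)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    pattern: CA3PatternParams = field(default_factory=lambda: CA3PatternParams(duration_s=60.0))
    n_trials: int = 10
    seed: int = 0
    sample_step_ms: float = 0.025

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        for c in self.conditions:
            condition_params(c, custom=self.custom_stp if c == "custom" else None)

    def stp(self, condition: str, A: float = 1.0) -> STPParams:
        return condition_params(condition, A=A, custom=self.custom_stp)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "population" in d and isinstance(d["population"], dict):
            pop = dict(d["population"])
            if isinstance(pop.get("distribution"), dict):
                pop["distribution"] = WeightDistribution(**pop["distribution"])
            for key in ("attenuation_range", "jitter_range_ms"):
                if isinstance(pop.get(key), list):
                    pop[key] = tuple(pop[key])
            d["population"] = PopulationSpec(**pop)
        if isinstance(d.get("neuron"), dict):
            d["neuron"] = NeuronParams(**d["neuron"])
        if isinstance(d.get("pattern"), dict):
            d["pattern"] = CA3PatternParams(**d["pattern"])
        if isinstance(d.get("conditions"), list):
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ExperimentResult:
    """Per-trial table, aggregate table and run metadata.

    Aggregates are always recomputable from the per-trial table; ``save``
    writes both as CSV plus a JSON metadata snapshot.
    """

    name: str
    trials: pd.DataFrame
    aggregate: pd.DataFrame
    metadata: dict
    extras: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(out / f"{self.name}_trials.csv", index=False)
        self.aggregate.to_csv(out / f"{self.name}_aggregate.csv", index=False)
        with open(out / f"{self.name}_meta.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)


def _trial_seeds(master_seed: int, n: int) -> list:
    return np.random.SeedSequence(master_seed).spawn(n)


def _aggregate(trials: pd.DataFrame, by: list[str], value_cols: list[str]) -> pd.DataFrame:
    rows = []
    for keys, grp in trials.groupby(by, sort=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        row = dict(zip(by, keys))
        for col in value_cols:
            vals = grp[col].dropna().to_numpy()
            if vals.size == 0:
                row[f"{col}_mean"], row[f"{col}_sem"] = np.nan, np.nan
            else:
                row[f"{col}_mean"], row[f"{col}_sem"] = spikestats.mean_sem(vals)
        rows.append(row)
    return pd.DataFrame(rows)


def _metadata(config: ExperimentConfig, **extra) -> dict:
    from . import __version__

    md = {"config_digest": config.digest(), "seed": config.seed, "version": __version__}
    md.update(extra)
    return md


# ---------------------------------------------------------------------------
# clamp-mode protocols


def _clamp_trial_amplitudes(config: ExperimentConfig, condition: str, frequency: float, n_pulses: int, rng):
    """Per-pulse somatic clamp amplitudes for one trial (synchronous drive).

    With synchronous identical synapses the summed current is the shared
    active fraction scaled by the total effective conductance and driving
    force, so amplitudes come straight from the event-driven propagation.
    """
    params = config.stp(condition)
    pop = config.population.build(params, rng)
    driving = abs(config.population.hold_mv - config.population.reversal_mv)
    amps, normalized = train_amplitudes(params, n_pulses, frequency)
    total = float(np.sum(pop.effective_weights_ns))
    return amps * total * driving, normalized


def run_validation(config: ExperimentConfig = ExperimentConfig(), frequency: float = 100.0, n_pulses: int = 5) -> ExperimentResult:
    """Five-pulse 100 Hz clamp protocol for each condition.

    Emits per-trial absolute and normalized amplitude curves; the control
    curve facilitates throughout while the increased-release condition
    facilitates once and then depresses.
    """
    seeds = _trial_seeds(config.seed, config.n_trials)
    rows = []
    for condition in config.conditions:
        for trial, seed in enumerate(seeds):
            rng = np.random.default_rng(seed)
            amps, normalized = _clamp_trial_amplitudes(config, condition, frequency, n_pulses, rng)
            for i in range(n_pulses):
                rows.append(
                    {
                        "condition": condition,
                        "trial": trial,
                        "pulse": i + 1,
                        "amplitude_pa": amps[i],
                        "normalized": normalized[i],
                    }
                )
    trials = pd.DataFrame(rows)
    aggregate = _aggregate(trials, ["condition", "pulse"], ["amplitude_pa", "normalized"])
    return ExperimentResult("validation", trials, aggregate, _metadata(config, frequency=frequency, n_pulses=n_pulses))


def run_frequency_sweep(
    config: ExperimentConfig = ExperimentConfig(),
    frequencies=(5.0, 10.0, 20.0, 40.0, 80.0, 100.0, 150.0, 200.0),
    n_pulses: int = 10,
) -> ExperimentResult:
    """Ten-pulse clamp trains across a frequency range for each condition."""
    import warnings

    for f in frequencies:
        if not 5.0 <= f <= 200.0:
            warnings.warn(f"frequency {f} Hz outside the characterized 5-200 Hz range")
    seeds = _trial_seeds(config.seed, config.n_trials)
    rows = []
    for condition in config.conditions:
        for freq in frequencies:
            for trial, seed in enumerate(seeds):
                rng = np.random.default_rng(seed)
                amps, normalized = _clamp_trial_amplitudes(config, condition, freq, n_pulses, rng)
                for i in range(n_pulses):
                    rows.append(
                        {
                            "condition": condition,
                            "frequency_hz": freq,
                            "trial": trial,
                            "pulse": i + 1,
                            "amplitude_pa": amps[i],
                            "normalized": normalized[i],
                        }
                    )
    trials = pd.DataFrame(rows)
    aggregate = _aggregate(trials, ["condition", "frequency_hz", "pulse"], ["amplitude_pa", "normalized"])
    return ExperimentResult("frequency_sweep", trials, aggregate, _metadata(config, n_pulses=n_pulses))


# ---------------------------------------------------------------------------
# free-running protocols


def default_drives(config: ExperimentConfig, n_patterns: int = 5) -> list[SpikeTrain]:
    """The naturalistic drive set: synthetic CA3 patterns from seeds 1-5."""
    return [generate_pattern(config.pattern, seed=s) for s in FIXTURE_SEEDS[:n_patterns]]


def _free_run_metrics(config: ExperimentConfig, condition: str, drive: SpikeTrain, scale: float, jitter: bool, rng):
    params = config.stp(condition)
    pop = config.population.build(params, rng).scaled(scale)
    jrange = config.population.jitter_range_ms if jitter else (0.0, 0.0)
    events = jitter_events(drive.times_ms, jrange, n_synapses=pop.n, rng=rng)
    out, _ = run_free(pop, events, config.neuron, sample_step=config.sample_step_ms, duration_ms=drive.duration_ms)
    metrics = {
        "n_stimuli": drive.n,
        "n_output": out.n,
        "spike_probability": spikestats.spike_probability(out.n, drive.n),
        "isi_cv": spikestats.isi_cv(out) if out.n >= 3 else np.nan,
        "theta_probability": spikestats.band_probability(out, spikestats.THETA_BAND) if out.n >= 2 else np.nan,
        "gamma_probability": spikestats.band_probability(out, spikestats.GAMMA_BAND) if out.n >= 2 else np.nan,
        "mean_conductance_ns": float(np.sum(pop.effective_weights_ns)),
    }
    freqs = 1.0 / np.diff(out.times_s) if out.n >= 2 else np.array([])
    return metrics, freqs


def run_weight_sweep(
    config: ExperimentConfig = ExperimentConfig(),
    weight_scales=(0.5, 1.0, 2.0, 4.0, 8.0, 16.0),
    modes: tuple[str, ...] = ("synchronous", "asynchronous"),
    drives: list[SpikeTrain] | None = None,
) -> tuple[ExperimentResult, dict[tuple[str, str], SigmoidFit]]:
    """Spike probability vs uniform weight multiplier, with sigmoid fits.

    Drives default to the first naturalistic pattern (asynchronous trials
    re-jitter each synapse per event within the configured 0-9 ms range).
    Returns the result and one sigmoid fit per (condition, mode) keyed on
    mean total peak conductance.
    """
    if len(weight_scales) < 5:
        raise ValueError("need at least 5 weight scales spanning sub- to supra-threshold")
    if drives is None:
        drives = default_drives(config, n_patterns=1)
    seeds = _trial_seeds(config.seed, config.n_trials)
    rows = []
    for condition in config.conditions:
        for mode in modes:
            jitter = mode == "asynchronous"
            for scale in weight_scales:
                for trial, seed in enumerate(seeds):
                    rng = np.random.default_rng(seed)
                    drive = drives[trial % len(drives)]
                    metrics, _ = _free_run_metrics(config, condition, drive, scale, jitter, rng)
                    rows.append(
                        {"condition": condition, "mode": mode, "scale": scale, "trial": trial, **metrics}
                    )
    trials = pd.DataFrame(rows)
    aggregate = _aggregate(
        trials, ["condition", "mode", "scale"], ["spike_probability", "mean_conductance_ns"]
    )
    fits: dict[tuple[str, str], SigmoidFit] = {}
    for (condition, mode), grp in aggregate.groupby(["condition", "mode"], sort=False):
        fits[(condition, mode)] = fit_sigmoid(
            grp["mean_conductance_ns_mean"].to_numpy(), grp["spike_probability_mean"].to_numpy()
        )
    result = ExperimentResult("weight_sweep", trials, aggregate, _metadata(config), extras={"sigmoid_fits": fits})
    return result, fits


def run_natural_drive(
    config: ExperimentConfig = ExperimentConfig(),
    regime_scales: RegimeCalibration | dict[str, float] | None = None,
    drives: list[SpikeTrain] | None = None,
    jitter: bool = False,
) -> ExperimentResult:
    """Drive the neuron with the five naturalistic patterns in two regimes.

    For every regime x condition x pattern x trial the run records spike
    probability, output ISI CV and theta/gamma band probabilities; per-trial
    seeds are shared across conditions (paired design).  The result's
    ``extras`` hold pooled instantaneous frequencies per (regime, condition)
    and a table of paired condition comparisons (t-tests on the per-pattern
    means, Kolmogorov-Smirnov on the pooled frequency distributions).
    """
    if regime_scales is None:
        raise ValueError("regime_scales is required (use neuron.calibrate_regimes)")
    if isinstance(regime_scales, RegimeCalibration):
        scales = {
            "integrative": regime_scales.integrative_scale,
            "saturating": regime_scales.saturating_scale,
        }
    else:
        scales = dict(regime_scales)
    if drives is None:
        drives = default_drives(config)
    seeds = _trial_seeds(config.seed, len(drives) * config.n_trials)
    rows = []
    pooled: dict[tuple[str, str], list[np.ndarray]] = {}
    for regime, scale in scales.items():
        for condition in config.conditions:
            for ip, drive in enumerate(drives):
                for trial in range(config.n_trials):
                    rng = np.random.default_rng(seeds[ip * config.n_trials + trial])
                    metrics, freqs = _free_run_metrics(config, condition, drive, scale, jitter, rng)
                    rows.append(
                        {
                            "regime": regime,
                            "condition": condition,
                            "pattern": ip + 1,
                            "trial": trial,
                            "scale": scale,
                            **metrics,
                        }
                    )
                    pooled.setdefault((regime, condition), []).append(freqs)
    trials = pd.DataFrame(rows)
    value_cols = ["spike_probability", "isi_cv", "theta_probability", "gamma_probability"]
    aggregate = _aggregate(trials, ["regime", "condition"], value_cols)
    per_pattern = _aggregate(trials, ["regime", "condition", "pattern"], value_cols)
    pooled_freqs = {k: (np.concatenate(v) if v else np.array([])) for k, v in pooled.items()}
    comparisons = _condition_comparisons(per_pattern, pooled_freqs, config.conditions, list(scales))
    result = ExperimentResult(
        "natural_drive",
        trials,
        aggregate,
        _metadata(config, regime_scales=scales, jitter=jitter),
        extras={"per_pattern": per_pattern, "pooled_frequencies": pooled_freqs, "comparisons": comparisons},
    )
    return result


def _condition_comparisons(per_pattern: pd.DataFrame, pooled_freqs, conditions, regimes) -> pd.DataFrame:
    """Paired per-pattern t-tests and pooled-distribution KS tests."""
    n_patterns = per_pattern["pattern"].nunique() if len(per_pattern) else 0
    if len(conditions) < 2 or n_patterns < 3:
        return pd.DataFrame()
    a, b = conditions[0], conditions[1]
    rows = []
    for regime in regimes:
        sub = per_pattern[per_pattern["regime"] == regime]
        for metric in ("spike_probability", "isi_cv", "theta_probability", "gamma_probability"):
            col = f"{metric}_mean"
            va = sub[sub["condition"] == a].sort_values("pattern")[col].to_numpy()
            vb = sub[sub["condition"] == b].sort_values("pattern")[col].to_numpy()
            report = spikestats.compare_conditions(vb, va, kind="paired-mean")
            rows.append(
                {
                    "regime": regime,
                    "metric": metric,
                    "test": "paired-t",
                    "statistic": report.statistic,
                    "p_value": report.p_value,
                    "significant": report.significant,
                    f"{a}_mean": float(np.mean(va)),
                    f"{b}_mean": float(np.mean(vb)),
                }
            )
        fa, fb = pooled_freqs.get((regime, a)), pooled_freqs.get((regime, b))
        if fa is not None and fb is not None and fa.size >= 3 and fb.size >= 3:
            report = spikestats.compare_conditions(fa, fb, kind="distribution")
            rows.append(
                {
                    "regime": regime,
                    "metric": "instantaneous_frequency",
                    "test": "kolmogorov-smirnov",
                    "statistic": report.statistic,
                    "p_value": report.p_value,
                    "significant": report.significant,
                    f"{a}_mean": np.nan,
                    f"{b}_mean": np.nan,
                }
            )
    return pd.DataFrame(rows)
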