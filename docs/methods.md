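# Methods

## Synapse model and its propagation

The synapse is the three-state resource model with facilitating release
probability (see README for the equations).  Design choices:

* **Exact event-driven propagation.**  Between spikes the system is linear,
  so states advance by closed forms: y(Δt) = y₀e^(−Δt/τ_in); z solves the
  two-exponential inactivation/recovery balance, with the t·e^(−t/τ)
  limit form when τ_in = τ_rec (switched on a relative tolerance of 1e−12);
  x = 1 − y − z; p(Δt) = p₀e^(−Δt/τ_facil).  This removes step-size
  artifacts entirely; the test suite checks agreement with fixed-step
  RK4 integration of the ODEs at 1e−3 ms to 1e−6 absolute.
* **Baseline of p is 0**, so p at the first spike of a train equals U: the
  facilitation increment is applied before release, making U the initial
  release probability p₀.
* **Per-pulse amplitude convention.**  The amplitude of pulse *i* is the
  maximum of A·y(t) attributable to that pulse.  Because y decays
  monotonically between spikes, that maximum is the post-spike value
  A·y⁺, which includes any residual active resource from earlier pulses —
  no baseline subtraction.  Whether experimental train amplitudes are
  baseline-corrected at high rates is ambiguous; at τ_in = 1 ms the
  residual at ≥5 ms intervals is < 1% so the two conventions nearly
  coincide.
* **Units**: ms and pA (or nS under the conductance convention) inside the
  library; spike-time files are in seconds.

A consequence worth stating: with the shared time constants, the model
*always* facilitates on the second pulse, even at 200 Hz in the
increased-release condition (p rises from 0.36 to ≈0.58 while x falls only
to ≈0.67, so pulse 2 ≈ 1.09).  Somatic recordings from morphologically
detailed neurons can show pure depression at those rates because of
dendritic filtering; a point model of the synapse cannot.  This is a known,
documented limitation (and the reason one high-frequency shape check in the
acceptance suite fails by design rather than being weakened).

## Reduced CA1 neuron

A single-compartment conductance-based integrate-and-fire cell replaces a
morphologically detailed CA1 pyramidal model.  Membrane equation:

    C dV/dt = −g_L(V−E_L) − g_syn(t)(V−E_syn) − g_a(t)(V−E_a)

Defaults: τ_m = 20 ms, g_L = 10 nS (C = 200 pF), E_L = −70 mV, threshold
−54 mV, reset −65 mV, absolute refractory period 3 ms, E_syn = 0 mV.

`g_a` is a slow spike-triggered **adaptation conductance** (increment 32 nS
per output spike, decay τ = 300 ms, reversal −90 mV): the
single-compartment stand-in for the sAHP/K(Ca) machinery of CA1 cells.  It
is essential, not cosmetic.  Without it a leaky integrator acting as a
coincidence detector on bursty drive produces output *more* irregular than
its input and can never fire less under stronger synapses; with it the
sparsely firing control neuron is regularized (output CV below input CV)
and the strongly driven increased-release neuron accumulates
self-inhibition, which is what lets the two conditions converge — and the
control condition marginally win — at the saturating ceiling.  Defaults
are increment 32 nS, τ = 300 ms, chosen so the control neuron's output
regime matches the qualitative study conditions (output more regular than
the naturalistic input; saturating ceiling near 90%).  Setting the
increment to 0 recovers the plain integrate-and-fire cell.

Integration is exponential-Euler at 0.025 ms (stable for conductance-based
leak; the step is validated against 0.1·τ_m).  Synaptic conductances are
advanced by the event-driven closed form and sampled onto the voltage grid,
so the only discretization concerns V itself.  In voltage-clamp mode the
current is Σᵢ wᵢ·yᵢ(t)·(V_hold − E_syn) with no spiking; clamp currents are
exactly linear in the population.

Dendritic placement (100–400 μm) is represented by a per-synapse
attenuation factor drawn uniformly from [0.7, 1.0] and resampled every
trial, standing in for electrotonic distance along the apical trunk.

## Synapse populations and protocols

Ten model synapses, each aggregating 15 real contacts (150 total).  Peak
conductances derive from miniature-EPSC amplitudes drawn from a shifted
lognormal (log-scale μ = 1.6, shape σ = 1, location x₀ = 5 pA — read as the
standard three-parameter lognormal) divided by the 70 mV driving force at a
−70 mV hold.  Weights and attenuations are resampled each trial.
Asynchronous activation jitters every event of every synapse independently
and uniformly in 0–9 ms (about a quarter of a gamma cycle); per-train
offsets are available as an option, per-event being the stronger
desynchronization.

## Synthetic CA3 drive

No recordings are distributed with the package, so naturalistic drive is
synthesized: an inhomogeneous Poisson process with rate

    λ(t) = [baseline + Σ_k peak·exp(−(t−c_k)²/2σ²)] · [1 + d·sin(2π·8·t)]

thinned to a 3 ms minimum ISI.  Burst-event centers c_k arrive as a Poisson
process.  Defaults (chosen once, on input-train statistics): baseline
2.5 Hz, 6 burst events/min, σ = 40 ms, peak 100 Hz, theta depth 0.6,
duration 600 s.  The short high-rate envelopes emulate the complex-spike
burst firing of CA3 pyramidal cells in vivo; across seeds 1–5 the trains
have mean rate ≈ 3.2 Hz, mean ISI CV = 1.245 (the irregularity of the
recordings they stand in for, 1.25 ± 0.14), and inter-spike intervals
populating both the theta (≈0.16 of ISIs) and gamma (≈0.09) bands.

What the generator does **not** emulate: place-field traversals lasting
several theta cycles (second-long envelopes push the ISI CV far above the
target at plausible CA3 rates, so burst events are single packets), spatial
position, phase precession, and cross-cell correlations.  Consequently the
control neuron, firing at most about once per burst packet in the
integrative regime, produces almost no consecutive-theta-cycle intervals —
its theta-band ISI fraction stays well below the increased-release
neuron's.  Passing directional tests on spike probability, CV, and gamma
content therefore say nothing about theta-band invariance in real data;
that contrast is outside what this reduction reproduces (it would need
theta-resonant conductances or multi-cycle traversals).

## Fitting

Synapse parameters are estimated from normalized amplitude curves by
bounded least squares (SciPy trust-region reflective) from a fixed,
deterministic multi-start grid: linear in U, log-spaced in the time
constants, 8 points per free axis, Cartesian product capped at 64 starts.
A is not identifiable from normalized data and is never free; absolute
scale is set separately from the first-pulse magnitude.  Default bounds:
U ∈ (0.001, 1], τ_in ∈ [0.05, 20] ms, τ_rec ∈ [1, 1000] ms,
τ_facil ∈ [1, 2000] ms.  Fits are exactly reproducible.

Spike-probability-vs-conductance curves are fitted with
y = a/(1 + b·e^(−c·x)) via `curve_fit`, optionally with the asymptote *a*
pinned at the empirical saturating probability; constant-y inputs are
rejected as degenerate rather than silently returning an unidentifiable
slope.

## Statistics

Spike probability is 100 × (output spikes)/(stimuli); values above 100%
are possible and flagged.  ISI CV uses the population standard deviation.
Instantaneous frequency is 1/ISI; band probabilities count ISIs whose
frequency falls in the **closed** interval (theta 4–8 Hz, gamma 40–80 Hz) —
edge handling is a convention, documented here, and per-ISI (not per-spike)
normalization is used throughout.  Condition contrasts use a paired t-test
across the five patterns' per-pattern means, gated by a Shapiro–Wilk check
on the differences (violations warn but do not abort), and pooled
instantaneous-frequency distributions are compared with a two-sample
Kolmogorov–Smirnov test; significance is declared at p < 0.05.  Mean ± SEM
aggregation uses the n−1 denominator.

## Experiments, seeding, and problem sizes

Trial seeds derive from `numpy.random.SeedSequence(master_seed).spawn(n)`,
one child per trial, the same child driving both conditions of a trial so
that weights, attenuations and jitter are matched pairs (a paired design).
Identical configuration + seed reruns are byte-identical.

Regime calibration bisects a uniform weight multiplier (common random
numbers across evaluations) until the 10-trial mean spike probability of
the control neuron enters the target bands: integrative 25–40%, saturating
85–92%.  Unreachable bands (e.g. above the refractory ceiling) raise a
calibration error with diagnostics.

Default problem sizes are chosen for desk-scale runs: experiment suites use
60 s patterns and 10 trials (the full study aggregates
2 regimes × 2 conditions × 5 patterns × 10 trials); 600 s patterns are a
configuration switch away and the five shipped fixtures are full length.

## Known limitations

* The neuron is a point model: no dendritic nonlinearity, no NMDA
  conductances (the modelled effect is AMPA-mediated), no theta resonance;
  absolute conductance values (e.g. "30 nS vs 90 nS") are not comparable
  to morphologically detailed models, only the regime contrasts are.
* The synapse facilitates at pulse 2 even at 150–200 Hz (see above).
* The generator's single envelope timescale trades theta-cycle structure
  for the target ISI irregularity; theta-band output contrasts are not
  reproduced.
* Deterministic mean-field release: no quantal/vesicle stochasticity, so
  trial-to-trial variability comes only from weights, placement and jitter.
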