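# Methods

This note documents the models, the numerical choices, and the open
design decisions behind the package, and states what the synthetic
components do and do not emulate.

## Neuron element

Each neuron element is a leaky integrate-and-fire membrane with
conductance-based multi-synapses and spike-frequency adaptation,
integrated by forward Euler on a fixed grid (dt = 0.1 ms by default,
mimicking a clocked switched-capacitor circuit; network experiments use
dt = 0.5 ms, see *Problem sizes*). Per step: pending synaptic events
are injected (simultaneous events sum linearly), the membrane is
updated (held at reset while refractory), a threshold crossing emits a
spike (reset, refractory start, SFA increment, STP update), then all
conductances decay by their exact exponential factor. The membrane is
clamped to the interval spanned by the reversal potentials — explicit
Euler could otherwise overshoot during extreme conductance transients.

A multi-synapse accumulates all inputs of one type on a single
conductance with instantaneous onset and exponential decay; because
inject and decay commute to the closed form
g(t) = Σᵢ aᵢ·exp(−(t−tᵢ)/τ), the discrete update is exact for the
conductances and approximate only for the membrane. NMDA synapses
scale their current by a piecewise-linear voltage dependence clamped at
its end factors; the default three-point curve (−80 mV → 0,
−40 mV → 0.5, 0 mV → 1) approximates the Mg²⁺-block sigmoid.

Presynaptic short-term plasticity follows the Tsodyks–Markram
recurrences. Between spikes u relaxes to U (τ_facil) and x to 1
(τ_rec); a spike applies u ← u + U(1−u) in facilitating modes and
x ← x(1−u) in depressing modes. The transmitted state is the 6-bit
quantization round(u·x·63) after the full update; the continuous
variables are retained internally and re-quantized at each
transmission. Synaptic efficacy is the integer product of this state
with the 6-bit routing weight, scaled to nS by the target synapse's
quantum (g_max/3969, so a full 63×63 product delivers the configured
maximum conductance).

The vectorized network stepper (numba) reproduces the scalar reference
implementation spike-for-spike (tested); recurrent spikes are routed
with one time-step latency, and the culture→hardware transport delay is
a configurable loop delay (default 1 ms).

## Network operating point

The deployed structure is fixed: 2880 neurons (9 chips × 10 groups ×
32), one excitatory recurrent population at p = 0.007 (mean out-degree
≈ 20), 25 Poisson background sources at 10 Hz connected with p = 0.3
and g = 20 nS, and 60 culture input channels each targeting a 20%
random subset of the network. The dynamical biases that put this
structure into the brief-population-spike regime are not fully
constrained, and were chosen once, by parameter scan, to reproduce that
regime qualitatively:

| parameter | value | role |
| --- | --- | --- |
| C | 1.0 nF | with g_L, sets single-event EPSPs to ~6 mV so synchronization requires coincidence |
| g_L | 140 nS | holds the background-driven mean membrane ~8 mV below threshold |
| SFA increment / τ | 10 nS / 1 s | slow after-spike inhibition; spaces population spikes |
| recurrent g | 25 nS | ignition gain of the population spike |
| recurrent STP | depression, U = 0.4, τ_rec = 500 ms | terminates the population spike by resource depletion |

This yields a quiescent baseline (~0.15–0.2 Hz per neuron),
spontaneous population spikes at ~0.05–0.1 Hz with peak rates tens of
times the baseline, and reliable conversion of an afferent culture
burst into a hardware population spike (30/30 across tested seeds).
A degree-preserving scale-down (288 neurons, p = 0.07) preserves this
regime and is the default for closed-loop experiments.

## Culture surrogate

The surrogate provides exactly the statistical structure the
closed-loop experiments rely on, and nothing deeper:

* response probability: logistic in amplitude (A₅₀ = 600 mV,
  k = 120 mV), multiplied by a post-burst recovery 1 − e^{−Δt/τ_b}.
  τ_b = 500 ms keeps the achievable response probability ≥ ~0.96 at
  the default 2-s pacing, so the estimator's stationary value matches
  the logistic law within ±0.05 over the controllable range;
* evoked latency: latency_base − latency_gain·(A − A₅₀) with
  latency_base = 120 ms, gain = 0.08 ms/mV, floor 20 ms, 10-ms jitter
  — higher amplitudes synchronize earlier;
* recruitment: electrodes fire in one of two template permutations
  (1.5 ms spacing, 0.5 ms jitter, ~3 spikes each over ~60 ms), the
  active template selected by an exponentially weighted estimate
  (τ = 60 s) of the recent evoked-response rate crossing 0.5 — so
  sustained high- and low-level control exercise distinct propagation
  paths;
* a direct-response volley inside the first 15 ms, sparse background
  spiking (0.2 Hz/electrode) and Poisson spontaneous bursts
  (0.05 Hz).

What it does **not** model: biophysics of cultured networks, electrode
drift, bursting rate adaptation over hours, spatial correlations
beyond the two templates, or any dependence of burst *size* on
amplitude (deliberately level-independent). Passing closed-loop tests
therefore demonstrate the control and analysis chain against a plant
with the assumed logistic/latency/template laws — not that a living
culture obeys those laws.

## Controller and estimator

The estimator is the exponentially weighted recursion with τ = 250 s
(equivalent to the explicit weighted sum; tested to 1e-12). The
controller is the standard PID form on the probability error with
gains g_P = 400 mV, g_I = 80 mV, g_D = 0 per unit error, output
clamped to the 100–1150 mV stimulator range. By default the integral
accumulates even while the output is clamped — under persistent error
the command rails at exactly 100/1150 mV and control is lost until the
integral unwinds, reproducing the deployed behavior.

For the tracking and two-level experiment designs the provided
`error_sum_clamp` (±3, i.e. ±240 mV of integral authority) is enabled:
a τ = 250 s estimate of a sinusoidal target of amplitude 0.3 requires
the plant probability to overdrive by a factor sqrt(1+(ωτ)²) — beyond
P = 1 near the peaks for any period shorter than ~1 hour — and an
unclamped integral winds up during those episodes and drives the
amplitude rail-to-rail. The clamp bounds the windup while leaving the
small-signal behavior identical. The baseline amplitude is calibrated
open-loop before each experiment (grid search for the amplitude whose
empirical response rate is closest to the mid-range target).

The default circuit reads the *hardware* network's responses while
stimulating the *culture* (indirect control); the read side is
configurable.

## Detection chain

Spike detection: per-channel threshold at −6× the SD of the first 2 s,
negative-going crossings, 6-ms refractory. Burst detection: population
spike counts in 25-ms bins anchored at recording start; threshold
ceil(0.25 × active electrodes) (= 15 of 60); consecutive
supra-threshold bins merge, the burst time is the first bin's start and
the amplitude the maximal bin. Evoked window (10, 800] ms after the
most recent stimulus; each stimulus claims at most its first burst.
Recruitment order: first spike per electrode after the 15-ms direct
exclusion, ties broken by ascending electrode id, truncated to depth 5.
Population spikes in rate traces must exceed 5× the iteratively
re-estimated non-peak baseline **and** an absolute floor of 10 Hz per
neuron (a quarter of the population in one 25-ms bin) so stray spikes
on a silent background do not count.

## Problem sizes and numerics

Closed-loop experiments default to the 288-neuron degree-preserving
network at dt = 0.5 ms: a 30-min coupled run executes in ~10 s, and
five-seed experiment batteries run in minutes. The membrane time
constants (≥ 4 ms effective) remain well resolved at this step; the
single-neuron convergence test checks that halving dt moves spike
times by less than one coarse step. Conductance decays use exact
exponential factors at any dt. All randomness (connectivity,
background playback, surrogate draws, readout subset) derives from
explicit seeds; a run is bitwise reproducible given its seed and call
sequence.

Experiment durations are scaled versions of the hours-long originals:
tracking uses a 900-s sine over 30 min (evaluated after the first
period); two-level control uses 10-min blocks. The two-level analysis
uses full blocks, transients included.

## Known limitations

* The hardware-side recruitment order carries weak structure: a
  population spike recruits near-synchronously, so path separation is
  demonstrated on the culture (stimulated) side.
* No long-term plasticity (short-term effects only, by design); no
  arbiter/bandwidth contention between chips; chip/group structure is
  bookkeeping.
* The logistic/latency/template laws of the surrogate are assumptions,
  not fits to recordings.
* Forward Euler with voltage clamping is first-order; spike times
  carry O(dt) bias (consistent between scalar and vectorized paths).
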