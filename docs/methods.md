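# Methods

This note documents the models behind `mocsim`: what is simulated, which
parameters matter, how the free parameters were calibrated, the numerical
choices, and where the simplifications are known to matter.

## Presynaptic spike trains (`mocsim.trains`)

The conductance-clamp paradigms are driven by ensembles of 80 independent
500-ms trials of tonic presynaptic firing, emulating T-stellate-like
"sustained chopper" activity. Only ensemble mean rates (and their standard
errors) are constrained by data, so the interval statistics are a modelling
choice:

- Inter-spike intervals are *jittered-regular*: base interval `1000/rate` ms
  multiplied by `max(1 + isi_cv · z, ε)` with `z ~ N(0,1)` and floored at an
  absolute refractory period (default 1 ms). The default `isi_cv = 0.15`
  expresses the regularity of sustained choppers; a Poisson process would
  overstate their irregularity. `isi_cv` is exposed as a parameter because
  the true interval distributions are unpublished.
- The first spike of each train is drawn uniformly within one mean interval
  of stimulus onset, desynchronizing the inputs without imposing a
  biological onset latency (none is published).
- Per-trial target rates are Gaussian around the paradigm mean
  (41.1 / 111 / 176 Hz) with between-trial SD = printed SEM × √80
  (2 SEM ≈ 4.5–9 Hz), which reproduces the printed 80-trial ensemble SEMs
  (±0.5 / ±1 / ±1 Hz) by construction.

What these trains do *not* emulate: auditory-nerve-driven temporal structure,
onset latency and rate adaptation of real T-stellate responses, or any
correlation between inputs. Tests passing on these ensembles therefore
validate the pipeline's statistics, not the fidelity of VCN/IC spike timing.

## Short-term plasticity (`mocsim.stp`)

Weights are a function of pulse index only (frequency-invariant), exactly as
fitted to normalized tetanus EPSC amplitudes; the first pulse is index 0 with
weight exactly 1. Facilitation: `Fac_max + A e^(−n/τ)` (2.43, −1.42, 12.9).
Depression: `Dep_max + A₁ e^(−n/τ₁) + A₂ e^(−n/τ₂)` (0.309, 0.443, 0.771,
0.248, 4.10). Time "constants" are in pulse-index units.

Recovery after a tetanus is a single exponential toward baseline 1 with
τ = 3.5 s (depression) or 4.5 s (facilitation). Because trains last ≤ 1 s and
τ_recovery is seconds, within-train recovery is neglected: recovery dynamics
apply only between a tetanus and later test pulses. The end-of-train state
defaults to the mean of the last three weights.

Known limitation: the weight functions were fitted at 20–50 Hz presynaptic
rates and are extrapolated unchanged to the ~110 and ~176 Hz paradigms; at
such rates real synapses may show frequency-dependent plasticity that this
phenomenological model cannot express. There is deliberately no mechanistic
vesicle-pool model.

## Conductance waveforms (`mocsim.epsg`)

The unitary EPSG is `(1 − e^(−t/τ_rise)) e^(−t/τ_decay)` with
τ_rise = 0.27 ms, τ_decay = 1.9 ms. Its analytic peak is at
τ_rise·ln(1 + τ_decay/τ_rise) ≈ 0.563 ms with value ≈ 0.651; the kernel is
divided by this peak so that `g_max` (0.40 nS facilitating, 0.46 nS
depressing) is the unitary *peak* conductance — this matches how unitary
maximal conductances are measured, whereas the raw biexponential formula is
unnormalized. The peak-normalized kernel integral is ≈ 2.555 ms, so an
N-input, rate-r, steady-weight-w waveform has mean conductance
N·r·g_max·w·2.555 ms (used as an analytic check in the tests).

Numerics: sampling interval 0.02 ms (50 kHz, within the usual digitization
range); kernel truncated at 10·τ_decay; spike times snapped to the nearest
sample. Synthesis scatters weighted impulses and performs one convolution;
a brute-force per-spike path (`method="direct"`) is retained as an oracle
and agrees to < 1e−9 nS. Per-spike weight indices count spikes within one
trial of one input and reset across trials.

## Neuron model (`mocsim.neuron`)

An adaptive leaky integrate-and-fire neuron:

    C dV/dt = g_L (E_rest − V) + g_syn(t) (E_rev − V) + I_inj − w
    τ_w dw/dt = −w;   on spike: w += w_inc, V → V_reset, refractory hold

integrated with exponential Euler (exact for piecewise-constant conductance),
default dt = 0.02 ms. The synapse is rectifying: the synaptic term is zero
whenever V > E_rev (+10 mV), a binary idealization of the inward
rectification of GluA2-lacking Ca²⁺-permeable AMPA receptors (the published
I-V is plotted, not tabulated, so no graded rectification curve is fitted).

| parameter | value | origin |
|---|---|---|
| C_m | 36.5 pF | measured |
| R_m | 123 MΩ | measured |
| E_rest | −80.4 mV | measured |
| V_thresh | −71.37 mV | calibrated |
| V_reset | −96.35 mV | calibrated (deep reset standing in for the AHP) |
| refractory | 4.43 ms | calibrated |
| w_inc | 35.17 pA | calibrated |
| τ_w | 178.5 ms | calibrated |
| E_rev | +10 mV | measured |
| block_i_threshold | 1600 pA | chosen (see below) |
| block_window | 5 ms | chosen |

**Calibration.** V_thresh, V_reset, refractory, w_inc and τ_w are not
measurable from the published data, so `calibrate()` fits them by
Nelder-Mead against the printed intrinsic measurements: the zero-intercept
f-I slope (0.150 Hz/pA, 500-ms steps, 100–900 pA, with a mild per-point
linearity penalty) and the adaptation ratios (0.69 at 900 pA weighted
strongly, 0.86 at 200 pA weakly). The shipped defaults are the frozen result
(slope 0.155, ratio 0.655 at 900 pA) so re-running the search is optional.
The model's 200-pA adaptation ratio (≈ 0.95) overshoots the measured 0.86:
a hard-threshold LIF reaches its quasi-steady rate too quickly at
near-rheobase drives, a known limitation of the model class. The biphasic
after-hyperpolarization waveform is not modeled (it does not enter any
quantity analyzed); the deep reset captures its net effect on interval
statistics.

**Depolarization block.** Real neurons stop spiking under extreme sustained
drive (Na-channel inactivation): observed with multi-nA current steps and
with 80 facilitating inputs at the high-rate paradigm. A hard-reset LIF
never fails to repolarize, so block cannot be expressed as a voltage
criterion on V itself. It is instead declared when the adaptation-corrected
drive current, `g_syn(t)·(E_rev − V_thresh) + I_inj − w(t)`, stays above
`block_i_threshold` continuously for more than `block_window`. The threshold
(1600 pA) was placed between the strongest non-blocking regimes (900-pA
steps; 80 depressing inputs at ~180 Hz, ≈ 1.3 nA transient) and the blocking
regimes (2–4 nA steps; 80 facilitating inputs at ~180 Hz, ≈ 1.7–2.9 nA
sustained). After block onset the membrane continues to integrate but emits
no spikes. Blocked trials are summarized with the extrapolation rule: mean
instantaneous frequency of pre-block spikes, halved, as the spike count per
500-ms trial.

**Simulated cohorts.** "N neurons" means N model instances whose passive
parameters are jittered by the printed SEMs (C_m ± 1.6 pF, R_m ± 9 MΩ,
E_rest ± 0.8 mV), each driven by an independently seeded input ensemble.
Cohorts default to 6 instances. Seed fan-out uses `numpy.random.SeedSequence`
spawning, so every experiment is reproducible from one master seed.

## Analysis conventions (`mocsim.analysis`)

- Instantaneous rate = reciprocal of each inter-spike interval; window
  statistics average those reciprocals.
- Adaptation ratio = mean instantaneous rate of the last five spikes over
  that of spikes #5–10 (1-based); responses with fewer than 15 spikes are
  excluded. The initial window is configurable because the source
  measurements describe it both as spikes #1–5 and #5–10 in different
  places; #5–10 is the default.
- Double-exponential decay fits report
  τ_w = τ_fast·%A_fast + τ_slow·(1 − %A_fast) with
  %A_fast = A_fast/(A_fast + A_slow); ill-conditioned double fits
  (τ_fast ≈ τ_slow or non-convergence) fall back to single with a warning.
- Histogram fits (mEPSC inter-event intervals, 0.02-s bins anchored at 0)
  are least squares on bin counts with τ constrained positive, matching how
  binned distributions are usually fitted; a maximum-likelihood route
  (`method="mle"`) is available as a cross-check.
- Spike detection in voltage traces: upward crossing of −20 mV with peak
  localization.

## Synthetic data (`mocsim.synthetic`)

- EPSC tetanus trains: stimulus-locked biexponential EPSCs whose peak
  magnitudes follow the plasticity weights, with optional per-sweep
  multiplicative variability and additive trace noise; sweep averaging
  emulates 20-sweep averages.
- mEPSC recordings: Poisson event times (mean inter-event interval 0.20 s;
  380 s duration gives ~1900 events), amplitudes from a log-normal truncated
  to 27.2–146.9 pA by resampling, with (μ, σ) solved numerically so the
  truncated distribution has median 52.5 pA and mean 57.5 pA (the family is
  a choice; only mean > median — right skew — is constrained by data).
  Events are rendered with an instantaneous rise and double-exponential
  decay (τ_fast 0.17 ms carrying 89% of the amplitude, τ_slow 1.72 ms).
  Not emulated: series-resistance filtering, capacitive transients, or
  colored electrode noise.
- Recovery protocols: test-pulse amplitudes at doubling intervals
  0.1–25.6 s after a 20-pulse tetanus, from the recovery model plus
  optional noise, normalized to the first tetanus pulse.

## Problem sizes and runtime

The default experiment sizes are those of the emulated study — 80-trial
ensembles, 10/20/40/80 inputs, 500-ms trials, 6-instance cohorts — and run
in seconds on one CPU at dt = 0.02 ms, so nothing is scaled down. Halving dt
changes spike counts by at most one across the standard paradigms.

## Known limitations

1. **Conductance-driven firing rates run high.** The LIF reproduces the
   *current*-step f-I relation by construction, but real MOC neurons fired
   ~25% below their own f-I line when the same mean drive arrived as a
   fluctuating synaptic conductance (e.g., ≈ 48 Hz at a mean drive of
   ≈ 420 pA from 80 depressing inputs at ~180 Hz). The model lacks the
   threshold accommodation / sodium-channel dynamics behind that
   suppression, and threshold-crossing rectification of conductance
   fluctuations adds further spikes, so it overshoots such paradigms by
   roughly 20–50%.
2. **First-spike latencies are near-immediate.** Every input's first pulse
   carries full weight within one mean interval of onset, so the onset
   conductance burst (hundreds of pA for ≥ 20 inputs) crosses threshold
   within a few ms, whereas recorded latencies were tens of ms. Matching
   them would require presynaptic onset statistics or postsynaptic
   accommodation dynamics that are not published.
3. The plasticity weight functions are extrapolated above the 20–50 Hz
   range they were fitted at.
4. The model is a point neuron: conductances are injected "at the soma",
   which the dynamic-clamp technique itself shares, but dendritic synaptic
   processing is absent by construction.
5. Inhibition and neuromodulation are out of scope (the emulated recordings
   blocked inhibition pharmacologically).
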