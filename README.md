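# mocsim

Simulation and analysis of synaptic integration in **medial olivocochlear
(MOC) efferent neurons** — the brainstem cholinergic neurons that project to
cochlear outer hair cells and control cochlear gain. MOC neurons receive
excitatory input from two pathways with opposite short-term plasticity: an
ascending, reflex pathway from the ventral cochlear nucleus (VCN, strongly
**depressing**) and a descending pathway from the inferior colliculus (IC,
strongly **facilitating**, augmentation-like). `mocsim` reproduces, at desk
scale, the conductance-clamp approach used to study how these inputs set the
onset and dynamic range of MOC firing, together with the quantification
pipeline around it.

The package is aimed at cellular/synaptic electrophysiologists and
computational neuroscientists who want a tested, scriptable implementation of
this kind of experiment: every input is synthetic and fully parameterized, so
each stage can be validated against known ground truth.

## What is modeled

**Per-pulse short-term plasticity.** During a tetanus, the n-th EPSG of one
input is scaled by a frequency-invariant weight (pulse 0 has weight exactly 1):

- facilitation: w(n) = Fac_max + A·e^(−n/τ), with Fac_max = 2.43, A = −1.42, τ = 12.9
- depression: w(n) = Dep_max + A₁·e^(−n/τ₁) + A₂·e^(−n/τ₂), with
  Dep_max = 0.309, A₁ = 0.443, τ₁ = 0.771, A₂ = 0.248, τ₂ = 4.10

The **plasticity index** of a 20-pulse train is mean(last 3)/first for
depression and mean(last 3)/mean(first 3) for facilitation. Recovery back to
baseline after a tetanus is a single exponential (τ ≈ 3.5 s depression,
≈ 4.5 s facilitation).

**Conductance waveforms.** Tonic presynaptic spike trains (jittered-regular
ISIs; ensembles of 80 trials at ~41, ~111 or ~176 Hz) are convolved with the
unitary EPSG kernel (1 − e^(−t/τ_rise))·e^(−t/τ_decay) (τ_rise = 0.27 ms,
τ_decay = 1.9 ms, peak-normalized, G_max 0.40/0.46 nS for
facilitating/depressing inputs) and weighted by the plasticity functions.

**Neuron model.** An adaptive leaky integrate-and-fire point neuron
(C_m = 36.5 pF, R_m = 123 MΩ, E_rest = −80.4 mV) calibrated so that 500-ms
current steps reproduce the measured zero-intercept f-I slope
(0.150 Hz/pA over 100–900 pA) and spike-frequency-adaptation ratio
(≈ 0.69 at 900 pA). Synaptic current is g(t)·(E_rev − V) with E_rev = +10 mV
and rectification (zero above E_rev), matching the calcium-permeable AMPA
receptors at these synapses. Depolarization block under extreme drive is
detected and handled with the halved-instantaneous-rate extrapolation rule.

**Analysis toolbox.** Linear f-I fits, adaptation ratio, firing sensitivity
(spikes per added input), first-spike latency, single/double exponential
decay fits with weighted τ, mEPSC inter-event-interval histogram fits and
amplitude statistics.

## Worked example

```python
from mocsim import (DepressionParams, FacilitationParams, weight_sequence,
                    plasticity_index, NeuronParams, run_current_clamp,
                    fi_slope, adaptation_ratio, ParadigmConfig, run_experiment)
from mocsim.neuron import fi_curve

dep = plasticity_index(weight_sequence(20, DepressionParams()), "depressing")
fac = plasticity_index(weight_sequence(20, FacilitationParams()), "facilitating")
print(f"plasticity index: depressing {dep:.2f}, facilitating {fac:.2f}")

params = NeuronParams()
currents, rates = fi_curve(params)
slope = fi_slope(currents, rates, force_zero_intercept=True).params["slope"]
trace = run_current_clamp(params, [900.0])[0]
print(f"f-I slope {slope:.3f} Hz/pA; adaptation ratio at 900 pA "
      f"{adaptation_ratio(trace.spike_times):.2f}")

cfg = ParadigmConfig(n_inputs=20, rate_paradigm="high",
                     plasticity="depressing", n_instances=6, seed=1)
res = run_experiment(cfg)
print(f"20 depressing inputs @ ~180 Hz: {res.mean_count:.1f} +/- "
      f"{res.sem_count:.1f} spikes per 500 ms trial")
```

Output:

```
plasticity index: depressing 0.31, facilitating 1.87
f-I slope 0.155 Hz/pA; adaptation ratio at 900 pA 0.65
20 depressing inputs @ ~180 Hz: 6.2 +/- 0.3 spikes per 500 ms trial
```

The two indices quantify ~70% depression of the ascending input versus
~1.9-fold facilitation of the descending input over a 20-pulse tetanus; the
f-I slope and adaptation ratio show the calibrated neuron encoding current
intensity nearly linearly with modest adaptation; and the cohort experiment
reproduces the sparse, reliable response to 20 depressing inputs at a high
presynaptic rate (a cohort here is six model instances with passive
parameters jittered by their published standard errors).

A command-line interface wraps the same functionality:

```bash
mocsim trains --paradigm low --n 80 --seed 1 --out trains.tsv
mocsim run --config examples/dep_high_20.yaml --out result.csv
mocsim sweep --plasticity depressing --rate low --seed 1
mocsim synth-data mepsc --duration 380 --seed 1 --out events.tsv
```

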