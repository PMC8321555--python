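"""Config-driven conductance-clamp experiments on a simulated cohort.

A cohort of ``n_instances`` model "neurons" (passive parameters jittered by
their published SEMs, each with its own input-ensemble seed) is driven by
synthesized conductance waveforms for a given paradigm: number of inputs,
presynaptic rate paradigm (low/mid/high), and plasticity kind (facilitating
or depressing), optionally combined with a second paradigm at a *different*
rate (so the two pathways are not artificially synchronized).

Outputs per instance: spike count (extrapolated through depolarization block
where it occurs), first-spike latency, failure and block flags; aggregated
as cohort mean +/- SEM.  `sweep` runs a family over input counts and fits
the firing sensitivity (spikes per added input).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .analysis import firing_sensitivity, first_spike_latency
from .epsg import ConductanceWaveform, SynapseSpec, combine, synthesize
from .errors import InvalidParameterError
from .neuron import NeuronParams, extrapolate_blocked_rate, run_conductance_clamp
from .trains import PARADIGM_RATES, generate_paradigm

__all__ = ["ParadigmConfig", "ExperimentResult", "run_experiment", "sweep"]

DEFAULT_INPUT_COUNTS = (10, 20, 40, 80)


@dataclass(frozen=True)
class ParadigmConfig:
    """One conductance-clamp paradigm applied to a simulated cohort."""

    n_inputs: int
    rate_paradigm: str  # 'low' | 'mid' | 'high'
    plasticity: str  # 'facilitating' | 'depressing'
    combine_with: "ParadigmConfig | None" = None
    n_instances: int = 6
    n_trials: int = 80
    duration: float = 500.0
    dt: float = 0.02
    seed: int | None = None
    base_params: NeuronParams = field(default_factory=NeuronParams)

    def __post_init__(self) -> None:
        if not 1 <= self.n_inputs <= self.n_trials:
            raise InvalidParameterError(
                f"n_inputs must be in [1, {self.n_trials}], got {self.n_inputs}"
            )
        if self.rate_paradigm not in PARADIGM_RATES:
            raise InvalidParameterError(f"unknown rate paradigm {self.rate_paradigm!r}")
        if self.plasticity not in ("facilitating", "depressing"):
            raise InvalidParameterError(f"unknown plasticity kind {self.plasticity!r}")
        if self.n_instances < 1:
            raise InvalidParameterError("n_instances must be >= 1")
        if (
            self.combine_with is not None
            and self.combine_with.rate_paradigm == self.rate_paradigm
        ):
            raise InvalidParameterError(
                "combined paradigms must use different rate paradigms "
                "(avoids artificial synchrony between pathways)"
            )


@dataclass(frozen=True)
class ExperimentResult:
    """Cohort outcome of one paradigm."""

    config: ParadigmConfig
    counts: np.ndarray  # spikes per trial (block-extrapolated), one per instance
    latencies: np.ndarray  # ms; NaN for failure trials
    failed: np.ndarray  # bool
    blocked: np.ndarray  # bool

    @property
    def mean_count(self) -> float:
        """Cohort mean spike count, failures counted as zero."""
        return float(self.counts.mean())

    @property
    def sem_count(self) -> float:
        n = self.counts.size
        return float(self.counts.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    @property
    def mean_count_excluding_failures(self) -> float:
        ok = ~self.failed
        return float(self.counts[ok].mean()) if ok.any() else 0.0

    @property
    def mean_rate(self) -> float:
        """Cohort mean firing rate in Hz (count / trial duration)."""
        return self.mean_count / self.config.duration * 1000.0

    @property
    def mean_latency(self) -> float:
        """Mean first-spike latency (ms) over non-failure instances (NaN if none)."""
        return float(np.nanmean(self.latencies)) if (~self.failed).any() else float("nan")

    @property
    def sem_latency(self) -> float:
        ok = ~np.isnan(self.latencies)
        n = int(ok.sum())
        return float(np.nanstd(self.latencies, ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "instance": np.arange(self.counts.size),
                "spike_count": self.counts,
                "first_spike_ms": self.latencies,
                "failed": self.failed,
                "blocked": self.blocked,
            }
        )


def _instance_waveform(config: ParadigmConfig, ensemble_seed: int,
                       combine_seed: int) -> ConductanceWaveform:
    ens = generate_paradigm(
        config.rate_paradigm, n_trials=config.n_trials,
        duration=config.duration, seed=ensemble_seed,
    )
    wave = synthesize(
        ens, SynapseSpec.from_kind(config.plasticity),
        n_inputs=config.n_inputs, dt=config.dt,
    )
    if config.combine_with is not None:
        sub = config.combine_with
        ens2 = generate_paradigm(
            sub.rate_paradigm, n_trials=sub.n_trials,
            duration=sub.duration, seed=combine_seed,
        )
        wave2 = synthesize(
            ens2, SynapseSpec.from_kind(sub.plasticity),
            n_inputs=sub.n_inputs, dt=config.dt,
        )
        wave = combine([wave, wave2])
    return wave


def run_experiment(config: ParadigmConfig) -> ExperimentResult:
    """Run one paradigm over the cohort: synthesize, inject, quantify.

    Seed fan-out: the master seed spawns one `SeedSequence` per instance,
    which in turn provides the passive-jitter stream, the primary ensemble
    seed and (if combining) the secondary ensemble seed.  The whole pipeline
    is deterministic for a fixed master seed.
    """
    root = np.random.SeedSequence(config.seed)
    counts, lats, failed, blocked = [], [], [], []
    for inst in root.spawn(config.n_instances):
        jit_ss, ens_ss, comb_ss = inst.spawn(3)
        params = config.base_params.jittered(np.random.default_rng(jit_ss))
        wave = _instance_waveform(
            config,
            ensemble_seed=int(ens_ss.generate_state(1)[0] % 2**31),
            combine_seed=int(comb_ss.generate_state(1)[0] % 2**31),
        )
        trace = run_conductance_clamp(params, wave)
        counts.append(extrapolate_blocked_rate(trace, duration=config.duration))
        lat = first_spike_latency(trace.spike_times)
        lats.append(np.nan if lat is None else lat)
        failed.append(trace.n_spikes == 0)
        blocked.append(trace.blocked_from is not None)
    return ExperimentResult(
        config=config,
        counts=np.asarray(counts, dtype=float),
        latencies=np.asarray(lats, dtype=float),
        failed=np.asarray(failed, dtype=bool),
        blocked=np.asarray(blocked, dtype=bool),
    )


def sweep(
    plasticity: str,
    rate_paradigm: str,
    input_counts: Sequence[int] = DEFAULT_INPUT_COUNTS,
    n_instances: int = 6,
    seed: int | None = None,
    combine_with: ParadigmConfig | None = None,
    base_params: NeuronParams | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Run one (plasticity, rate) family over input counts and fit FS.

    Returns ``(table, fs, fs_sem)``: the per-input-count cohort table, the
    firing sensitivity (slope of cohort-mean spike count vs input number)
    and its SEM estimated from per-instance slopes.
    """
    input_counts = list(input_counts)
    if len(input_counts) < 3:
        raise InvalidParameterError("firing-sensitivity sweep needs >= 3 input counts")
    results = []
    for n in input_counts:
        cfg = ParadigmConfig(
            n_inputs=n, rate_paradigm=rate_paradigm, plasticity=plasticity,
            combine_with=combine_with, n_instances=n_instances, seed=seed,
            base_params=base_params or NeuronParams(),
        )
        results.append(run_experiment(cfg))
    table = pd.DataFrame(
        {
            "n_inputs": input_counts,
            "mean_count": [r.mean_count for r in results],
            "sem_count": [r.sem_count for r in results],
            "mean_rate_hz": [r.mean_rate for r in results],
            "n_failures": [int(r.failed.sum()) for r in results],
            "n_blocked": [int(r.blocked.sum()) for r in results],
        }
    )
    fs = firing_sensitivity(table["n_inputs"], table["mean_count"]).params["slope"]
    per_instance = np.array(
        [
            firing_sensitivity(input_counts, [r.counts[i] for r in results]).params["slope"]
            for i in range(n_instances)
        ]
    )
    fs_sem = (
        float(per_instance.std(ddof=1) / np.sqrt(n_instances)) if n_instances > 1 else 0.0
    )
    return table, float(fs), fs_sem
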