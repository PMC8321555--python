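"""Synaptic conductance (EPSG) waveform synthesis.

Each presynaptic spike contributes a unitary conductance transient

    EPSG(t) = (1 - exp(-t / tau_rise)) * exp(-t / tau_decay)

peak-normalized to 1 and scaled by ``g_max`` times the short-term-plasticity
weight of that spike's pulse index within its trial.  Contributions sum
linearly across spikes and across inputs; the summed waveform is later
injected into the model neuron through a (by default rectifying) synapse
with reversal potential ``e_rev``.

``g_max`` is interpreted as the unitary *peak* conductance, matching how
unitary maximal conductances were measured; the kernel is therefore divided
by its analytic peak value before scaling.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import IncompatibleWaveformError, InvalidParameterError
from .stp import DepressionParams, FacilitationParams, PlasticityParams, weight_sequence
from .trains import SpikeTrain, TrainEnsemble

__all__ = [
    "EPSGKernel",
    "SynapseSpec",
    "ConductanceWaveform",
    "unitary_kernel",
    "synthesize",
    "combine",
    "waveform_to_tsv",
    "waveform_from_tsv",
]

DEFAULT_DT = 0.02  # ms (50 kHz), within the digitization range used
KERNEL_TAIL_TAUS = 10.0  # kernel truncated at 10 * tau_decay


@dataclass(frozen=True)
class EPSGKernel:
    """Unitary EPSG shape parameters (ms)."""

    tau_rise: float = 0.27
    tau_decay: float = 1.9

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise InvalidParameterError("require tau_decay > tau_rise > 0")

    @property
    def peak_time(self) -> float:
        """Analytic time of the kernel maximum: tau_rise * ln(1 + tau_decay/tau_rise)."""
        return self.tau_rise * math.log(1.0 + self.tau_decay / self.tau_rise)

    @property
    def peak_value(self) -> float:
        """Unnormalized kernel value at its peak."""
        t = self.peak_time
        return (1.0 - math.exp(-t / self.tau_rise)) * math.exp(-t / self.tau_decay)

    @property
    def normalized_integral(self) -> float:
        """Time integral (ms) of the peak-normalized kernel."""
        raw = self.tau_decay - (self.tau_rise * self.tau_decay) / (self.tau_rise + self.tau_decay)
        return raw / self.peak_value

    @property
    def length(self) -> float:
        """Default truncation length (ms)."""
        return KERNEL_TAIL_TAUS * self.tau_decay


@dataclass(frozen=True)
class SynapseSpec:
    """Unitary synapse description: strength, plasticity, reversal, rectification."""

    g_max: float  # nS, unitary peak conductance
    plasticity: PlasticityParams
    e_rev: float = 10.0  # mV
    rectifying: bool = True
    kernel: EPSGKernel = field(default_factory=EPSGKernel)

    def __post_init__(self) -> None:
        if self.g_max <= 0:
            raise InvalidParameterError("g_max must be positive")

    @classmethod
    def facilitating(cls, **kw) -> "SynapseSpec":
        """Descending (IC-like) input: G_max 0.40 nS, facilitating weights."""
        return cls(g_max=0.40, plasticity=FacilitationParams(), **kw)

    @classmethod
    def depressing(cls, **kw) -> "SynapseSpec":
        """Ascending (VCN-like) input: G_max 0.46 nS, depressing weights."""
        return cls(g_max=0.46, plasticity=DepressionParams(), **kw)

    @classmethod
    def from_kind(cls, kind: str, **kw) -> "SynapseSpec":
        if kind == "facilitating":
            return cls.facilitating(**kw)
        if kind == "depressing":
            return cls.depressing(**kw)
        raise InvalidParameterError(f"kind must be 'facilitating' or 'depressing', got {kind!r}")


@dataclass(frozen=True)
class ConductanceWaveform:
    """Uniformly sampled summed synaptic conductance (nS)."""

    dt: float  # ms
    g: np.ndarray  # nS
    e_rev: float = 10.0
    rectifying: bool = True
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "g", g)
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if g.size and g.min() < 0:
            raise InvalidParameterError("conductance must be non-negative")

    @property
    def duration(self) -> float:
        return self.g.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.g.size) * self.dt


def unitary_kernel(
    kernel: EPSGKernel | None = None, dt: float = DEFAULT_DT, length: float | None = None
) -> np.ndarray:
    """Sampled peak-normalized unitary EPSG, starting at t = 0 (value 0)."""
    kernel = kernel or EPSGKernel()
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if length is None:
        length = kernel.length
    if length < 5.0 * kernel.tau_decay:
        warnings.warn(
            f"kernel length {length} ms truncates the decay (< 5 * tau_decay)",
            stacklevel=2,
        )
    t = np.arange(int(round(length / dt))) * dt
    raw = (1.0 - np.exp(-t / kernel.tau_rise)) * np.exp(-t / kernel.tau_decay)
    return raw / kernel.peak_value


def _spike_indices(train: SpikeTrain, dt: float) -> np.ndarray:
    return np.round(train.times / dt).astype(np.intp)


def synthesize(
    ensemble: TrainEnsemble | Sequence[SpikeTrain],
    spec: SynapseSpec,
    n_inputs: int | None = None,
    dt: float = DEFAULT_DT,
    method: str = "conv",
) -> ConductanceWaveform:
    """Sum weighted unitary EPSGs over the first ``n_inputs`` trains.

    Within each train the k-th spike is scaled by the plasticity weight of
    pulse index k (weights reset between trains).  ``method='conv'`` scatters
    the weighted impulses and performs one convolution with the sampled
    kernel; ``method='direct'`` adds the kernel spike-by-spike and serves as
    the brute-force oracle.  Both produce identical waveforms to well below
    1e-9 nS.
    """
    trains = list(ensemble)
    if n_inputs is None:
        n_inputs = len(trains)
    if n_inputs < 0:
        raise InvalidParameterError("n_inputs must be >= 0")
    if n_inputs > len(trains):
        raise InvalidParameterError(
            f"n_inputs={n_inputs} exceeds the {len(trains)} trains available"
        )
    if method not in ("conv", "direct"):
        raise InvalidParameterError(f"unknown synthesis method {method!r}")
    trains = trains[:n_inputs]

    duration = trains[0].duration if trains else 500.0
    kern = unitary_kernel(spec.kernel, dt=dt)
    n_samples = int(round(duration / dt)) + kern.size

    prov = {
        "n_inputs": n_inputs,
        "g_max": spec.g_max,
        "plasticity": type(spec.plasticity).__name__,
    }
    if isinstance(ensemble, TrainEnsemble):
        prov["paradigm"] = ensemble.paradigm_label
        prov["seed"] = ensemble.seed

    if method == "conv":
        impulses = np.zeros(n_samples - kern.size + 1)
        for train in trains:
            if not train.n_spikes:
                continue
            w = spec.g_max * weight_sequence(train.n_spikes, spec.plasticity)
            np.add.at(impulses, _spike_indices(train, dt), w)
        g = np.convolve(impulses, kern)
        g = g[:n_samples]
        if g.size < n_samples:
            g = np.pad(g, (0, n_samples - g.size))
    else:
        g = np.zeros(n_samples)
        for train in trains:
            if not train.n_spikes:
                continue
            w = spec.g_max * weight_sequence(train.n_spikes, spec.plasticity)
            for idx, wk in zip(_spike_indices(train, dt), w):
                stop = min(idx + kern.size, n_samples)
                g[idx:stop] += wk * kern[: stop - idx]

    # Summation of non-negative kernels; clip float residue at zero.
    np.clip(g, 0.0, None, out=g)
    return ConductanceWaveform(
        dt=dt, g=g, e_rev=spec.e_rev, rectifying=spec.rectifying, provenance=prov
    )


def combine(waveforms: Iterable[ConductanceWaveform]) -> ConductanceWaveform:
    """Pointwise sum of compatible waveforms (same dt, e_rev, rectification)."""
    waveforms = list(waveforms)
    if not waveforms:
        raise InvalidParameterError("combine needs at least one waveform")
    first = waveforms[0]
    for w in waveforms[1:]:
        if w.dt != first.dt or w.e_rev != first.e_rev or w.rectifying != first.rectifying:
            raise IncompatibleWaveformError(
                "waveforms differ in dt, e_rev or rectification mode"
            )
    n = max(w.g.size for w in waveforms)
    g = np.zeros(n)
    for w in waveforms:
        g[: w.g.size] += w.g
    prov = {"combined": [w.provenance for w in waveforms]}
    return ConductanceWaveform(
        dt=first.dt, g=g, e_rev=first.e_rev, rectifying=first.rectifying, provenance=prov
    )


def waveform_to_tsv(wave: ConductanceWaveform, path: str | Path) -> None:
    """Two-column delimited text (time_ms, g_nS) plus a JSON metadata sidecar."""
    arr = np.column_stack([wave.times, wave.g])
    np.savetxt(path, arr, fmt="%.6f", delimiter="\t", header="time_ms\tg_nS")
    meta = {"dt": wave.dt, "e_rev": wave.e_rev, "rectifying": wave.rectifying,
            "provenance": wave.provenance}
    Path(str(path) + ".json").write_text(json.dumps(meta))


def waveform_from_tsv(path: str | Path) -> ConductanceWaveform:
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta_path = Path(str(path) + ".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        meta = {"dt": float(data[1, 0] - data[0, 0]) if len(data) > 1 else DEFAULT_DT,
                "e_rev": 10.0, "rectifying": True, "provenance": {}}
    return ConductanceWaveform(
        dt=meta["dt"], g=data[:, 1], e_rev=meta["e_rev"],
        rectifying=meta["rectifying"], provenance=meta.get("provenance", {}),
    )
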