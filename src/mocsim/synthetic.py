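"""Synthetic voltage-clamp and spontaneous-event data generators.

Everything the analysis pipeline consumes can be generated here with known
ground truth: tetanus EPSC trains shaped by the plasticity weight functions,
post-tetanus recovery protocols, and continuous miniature-EPSC (mEPSC)
recordings with exponential inter-event intervals, right-skewed amplitudes
and double-exponential event kinetics.

The mEPSC generator is calibrated to the published summary statistics:
median amplitude 52.5 pA, mean 57.5 pA, range 27.2-146.9 pA, mean
inter-event interval 0.20 s, decay tau_fast = 0.17 ms carrying 89% of the
amplitude and tau_slow = 1.72 ms.  The amplitude distribution family
(log-normal, truncated to the published range by resampling) is a modelling
choice; only its first moments are constrained by the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import lognorm

from .errors import FitFailureError, InvalidParameterError
from .stp import (
    DepressionParams,
    FacilitationParams,
    RecoveryParams,
    recovery_amplitude,
    weight_sequence,
)

__all__ = [
    "SyntheticEPSCTrain",
    "SyntheticMEPSCRecording",
    "MEPSCKinetics",
    "make_epsc_train",
    "make_mepsc_recording",
    "make_recovery_protocol",
    "solve_lognormal_amplitude_params",
]

# published mEPSC summary values used as generator defaults
MEPSC_MEAN_IEI = 0.20  # s
MEPSC_MEDIAN_AMP = 52.5  # pA
MEPSC_MEAN_AMP = 57.5  # pA
MEPSC_AMP_RANGE = (27.2, 146.9)  # pA


def _plasticity(kind: str):
    if kind == "facilitating":
        return FacilitationParams()
    if kind == "depressing":
        return DepressionParams()
    raise InvalidParameterError(f"kind must be 'facilitating' or 'depressing', got {kind!r}")


@dataclass(frozen=True)
class SyntheticEPSCTrain:
    """Stimulus-locked EPSC sweeps with known plasticity weights."""

    dt: float  # ms
    sweeps: np.ndarray  # (n_sweeps, n_samples), pA (negative-going events)
    stim_times: np.ndarray  # ms
    true_weights: np.ndarray
    true_amplitudes: np.ndarray  # (n_sweeps, n_pulses), pA magnitudes
    noise_sd: float
    kind: str

    @property
    def average(self) -> np.ndarray:
        """Across-sweep average trace (the paper-style 20-sweep average)."""
        return self.sweeps.mean(axis=0)

    def peak_amplitudes(self, trace: np.ndarray | None = None) -> np.ndarray:
        """Measured peak magnitude (pA) in a window after each stimulus."""
        y = self.average if trace is None else np.asarray(trace)
        isi = np.diff(self.stim_times).min() if self.stim_times.size > 1 else 20.0
        win = int(round(min(isi, 10.0) / self.dt))
        out = []
        for t0 in self.stim_times:
            i = int(round(t0 / self.dt))
            out.append(-y[i : i + win].min())
        return np.asarray(out)


def _epsc_kernel(dt: float, tau_rise: float = 0.27, tau_decay: float = 1.9,
                 n_taus: float = 10.0) -> np.ndarray:
    """Peak-normalized unitary EPSC shape (same biexponential form as the EPSG)."""
    t = np.arange(int(round(n_taus * tau_decay / dt))) * dt
    raw = (1.0 - np.exp(-t / tau_rise)) * np.exp(-t / tau_decay)
    return raw / raw.max()


def make_epsc_train(
    kind: str,
    n_pulses: int = 20,
    rate: float = 20.0,
    base_amplitude: float = 300.0,
    noise_sd: float = 0.0,
    n_sweeps: int = 1,
    sweep_cv: float = 0.0,
    dt: float = 0.02,
    seed: int | None = None,
) -> SyntheticEPSCTrain:
    """Simulate a voltage-clamp tetanus: EPSC amplitudes follow the weights.

    Each sweep renders ``n_pulses`` stimulus-locked negative-going EPSCs at
    ``rate`` Hz whose peak magnitudes are ``base_amplitude * weight(n)``,
    optionally scaled per sweep by multiplicative variability ``sweep_cv``
    and corrupted by additive Gaussian trace noise ``noise_sd`` (pA).
    """
    if n_pulses < 1:
        raise InvalidParameterError("n_pulses must be >= 1")
    if rate <= 0 or base_amplitude <= 0 or noise_sd < 0 or n_sweeps < 1:
        raise InvalidParameterError("invalid rate/base_amplitude/noise_sd/n_sweeps")
    params = _plasticity(kind)
    rng = np.random.default_rng(seed)

    weights = weight_sequence(n_pulses, params)
    stim_times = np.arange(n_pulses) * 1000.0 / rate
    kern = _epsc_kernel(dt)
    n_samples = int(round(stim_times[-1] / dt)) + kern.size + int(round(5.0 / dt))

    sweeps = np.empty((n_sweeps, n_samples))
    amps = np.empty((n_sweeps, n_pulses))
    for s in range(n_sweeps):
        scale = base_amplitude * max(1.0 + sweep_cv * rng.standard_normal(), 0.0)
        amps[s] = scale * weights
        trace = np.zeros(n_samples)
        for t0, a in zip(stim_times, amps[s]):
            i = int(round(t0 / dt))
            trace[i : i + kern.size] -= a * kern[: n_samples - i]
        if noise_sd > 0:
            trace += noise_sd * rng.standard_normal(n_samples)
        sweeps[s] = trace
    return SyntheticEPSCTrain(
        dt=dt, sweeps=sweeps, stim_times=stim_times, true_weights=weights,
        true_amplitudes=amps, noise_sd=noise_sd, kind=kind,
    )


# ---------------------------------------------------------------------------
# mEPSC recording

@dataclass(frozen=True)
class MEPSCKinetics:
    """Double-exponential mEPSC decay parameters."""

    tau_fast: float = 0.17  # ms
    tau_slow: float = 1.72  # ms
    fast_fraction: float = 0.89  # fraction of peak amplitude

    def kernel(self, dt: float, n_taus: float = 12.0) -> np.ndarray:
        """Unit-peak event shape: instantaneous rise, double-exponential decay."""
        t = np.arange(int(round(n_taus * self.tau_slow / dt))) * dt
        return (
            self.fast_fraction * np.exp(-t / self.tau_fast)
            + (1.0 - self.fast_fraction) * np.exp(-t / self.tau_slow)
        )


@dataclass(frozen=True)
class SyntheticMEPSCRecording:
    """Continuous current trace with embedded spontaneous events."""

    dt: float  # ms
    trace: np.ndarray | None  # pA, negative-going events; None if not rendered
    true_event_times: np.ndarray  # ms
    true_amplitudes: np.ndarray  # pA magnitudes
    kinetics: MEPSCKinetics
    noise_sd: float
    duration: float  # ms

    @property
    def n_events(self) -> int:
        return int(self.true_event_times.size)


def solve_lognormal_amplitude_params(
    mean: float = MEPSC_MEAN_AMP,
    median: float = MEPSC_MEDIAN_AMP,
    lo: float = MEPSC_AMP_RANGE[0],
    hi: float = MEPSC_AMP_RANGE[1],
) -> tuple[float, float]:
    """Solve (mu, sigma) of a log-normal whose [lo, hi]-truncated version
    has the requested mean and median.

    Solved numerically from the two moment conditions (truncated mean and
    median), starting from the untruncated closed forms
    ``mu = ln(median)``, ``sigma = sqrt(2 ln(mean/median))``.
    """
    if not lo < median < mean < hi:
        raise InvalidParameterError("require lo < median < mean < hi")

    def trunc_stats(mu, sigma):
        d = lognorm(s=sigma, scale=np.exp(mu))
        a, b = d.cdf(lo), d.cdf(hi)
        if b - a < 1e-12:
            return np.nan, np.nan
        med = d.ppf(a + 0.5 * (b - a))
        # truncated mean of a log-normal via the shifted-CDF identity
        d2 = lognorm(s=sigma, scale=np.exp(mu + sigma**2))
        m = np.exp(mu + sigma**2 / 2) * (d2.cdf(hi) - d2.cdf(lo)) / (b - a)
        return m, med

    def residuals(x):
        m, med = trunc_stats(x[0], abs(x[1]))
        if not np.isfinite(m):
            return [1e3, 1e3]
        return [(m - mean) / mean, (med - median) / median]

    x0 = (np.log(median), np.sqrt(2.0 * np.log(mean / median)))
    sol = least_squares(residuals, x0, xtol=1e-12, ftol=1e-12)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise FitFailureError("could not match the truncated log-normal moments")
    return float(sol.x[0]), float(abs(sol.x[1]))


def make_mepsc_recording(
    duration: float = 380.0,
    mean_iei: float = MEPSC_MEAN_IEI,
    amp_mean: float = MEPSC_MEAN_AMP,
    amp_median: float = MEPSC_MEDIAN_AMP,
    amp_range: tuple[float, float] = MEPSC_AMP_RANGE,
    kinetics: MEPSCKinetics | None = None,
    noise_sd: float = 2.0,
    dt: float = 0.05,
    seed: int | None = None,
    render: bool = True,
) -> SyntheticMEPSCRecording:
    """Simulate a spontaneous mEPSC recording.

    Event times follow a Poisson process (exponential inter-event intervals
    with mean ``mean_iei`` seconds over ``duration`` seconds, giving ~1900
    events at the defaults); amplitudes are truncated log-normal calibrated
    to the published mean/median/range; each event is rendered with the
    double-exponential kernel on a baseline with Gaussian noise.  With
    ``render=False`` only event times/amplitudes are generated (cheap, for
    event-statistics work).
    """
    if duration <= 0 or mean_iei <= 0 or noise_sd < 0:
        raise InvalidParameterError("invalid duration/mean_iei/noise_sd")
    kinetics = kinetics or MEPSCKinetics()
    rng = np.random.default_rng(seed)
    duration_ms = duration * 1000.0

    # exponential IEIs, in ms
    n_guess = int(duration / mean_iei * 1.3) + 50
    times = np.cumsum(rng.exponential(mean_iei * 1000.0, size=n_guess))
    while times.size and times[-1] < duration_ms:
        extra = times[-1] + np.cumsum(rng.exponential(mean_iei * 1000.0, size=50))
        times = np.concatenate([times, extra])
    times = times[times < duration_ms]

    mu, sigma = solve_lognormal_amplitude_params(amp_mean, amp_median, *amp_range)
    amps = np.empty(times.size)
    need = np.ones(times.size, dtype=bool)
    while need.any():  # truncation by resampling keeps the distribution proper
        draw = rng.lognormal(mu, sigma, size=int(need.sum()))
        ok = (draw >= amp_range[0]) & (draw <= amp_range[1])
        idx = np.flatnonzero(need)[ok]
        amps[idx] = draw[ok]
        need[idx] = False

    trace = None
    if render:
        kern = kinetics.kernel(dt)
        n_samples = int(round(duration_ms / dt)) + kern.size
        trace = noise_sd * rng.standard_normal(n_samples) if noise_sd > 0 else np.zeros(n_samples)
        for t0, a in zip(times, amps):
            i = int(round(t0 / dt))
            trace[i : i + kern.size] -= a * kern
        trace = trace[: int(round(duration_ms / dt))]

    return SyntheticMEPSCRecording(
        dt=dt, trace=trace, true_event_times=times, true_amplitudes=amps,
        kinetics=kinetics, noise_sd=noise_sd, duration=duration_ms,
    )


# ---------------------------------------------------------------------------
# recovery protocol

DEFAULT_RECOVERY_DTS = tuple(0.1 * 2**k for k in range(9))  # 0.1 .. 25.6 s


def make_recovery_protocol(
    kind: str,
    tetanus_pulses: int = 20,
    dts: Sequence[float] = DEFAULT_RECOVERY_DTS,
    noise_sd: float = 0.0,
    seed: int | None = None,
    recovery: RecoveryParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Test-pulse amplitudes (relative to the first tetanus EPSC) vs interval.

    The end-of-train state is the mean of the last three tetanus weights;
    test amplitudes relax back to 1 with the kind's recovery time constant
    (depression 3.5 s, facilitation 4.5 s), plus optional Gaussian noise.
    """
    dts = np.asarray(dts, dtype=float)
    if dts.size == 0 or np.any(dts < 0) or np.any(np.diff(dts) <= 0):
        raise InvalidParameterError("dts must be positive and increasing")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    params = _plasticity(kind)
    if recovery is None:
        recovery = (RecoveryParams.facilitating() if kind == "facilitating"
                    else RecoveryParams.depressing())
    weights = weight_sequence(tetanus_pulses, params)
    end_state = float(weights[-3:].mean())
    amps = np.array([recovery_amplitude(dt, end_state, recovery) for dt in dts])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        amps = amps + noise_sd * rng.standard_normal(amps.size)
    return dts, amps
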