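"""Electrophysiology quantification toolbox.

Spike statistics (adaptation ratio, first-spike latency, firing
sensitivity), linear f-I fits, single/double exponential decay fits with the
weighted time constant, and miniature-EPSC distribution analysis
(inter-event-interval histogram fit, amplitude summary).

Conventions
-----------
* Instantaneous rate is the reciprocal of each inter-spike interval; the
  "mean instantaneous rate over spikes a..b" is the mean of the reciprocals
  of the intervals among those spikes (1-based spike numbering).
* The adaptation ratio compares the last five spikes to spikes #5-10.
* Spike detection in voltage traces uses an upward crossing of -20 mV with
  peak localization.
* Histogram fits are least squares on bin counts (bins anchored at zero);
  a maximum-likelihood alternative is available where noted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DegenerateInputError,
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "FitResult",
    "EventSet",
    "fit_decay",
    "fi_slope",
    "adaptation_ratio",
    "firing_sensitivity",
    "first_spike_latency",
    "detect_spikes",
    "iei_histogram_fit",
    "amplitude_stats",
    "mean_instantaneous_rate",
]

MIN_SPIKES_FOR_ADAPTATION = 15


@dataclass(frozen=True)
class FitResult:
    """Parameters and goodness of fit of a linear or exponential model."""

    model: str  # 'single_exp' | 'double_exp' | 'linear'
    params: dict
    r_squared: float
    tau_weighted: float | None = None  # ms; double_exp only


@dataclass(frozen=True)
class EventSet:
    """Detected or simulated synaptic events: times (ms) and amplitudes (pA)."""

    event_times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "event_times", t)
        object.__setattr__(self, "amplitudes", a)
        if t.size != a.size:
            raise InvalidParameterError("event_times and amplitudes must match in length")
        if t.size and np.any(np.diff(t) <= 0):
            raise InvalidParameterError("event_times must be strictly increasing")
        if a.size and a.min() <= 0:
            raise InvalidParameterError("amplitudes are magnitudes and must be positive")

    @property
    def ieis(self) -> np.ndarray:
        """Inter-event intervals in ms."""
        return np.diff(self.event_times)

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_decay(
    t: Sequence[float],
    y: Sequence[float],
    model: str = "double",
) -> FitResult:
    """Fit the decay phase of a synaptic current with exponentials.

    ``t`` (ms) starts at the event peak; ``y`` (pA) may be of either sign.
    The double model is ``A_fast exp(-t/tau_fast) + A_slow exp(-t/tau_slow)``
    and additionally reports the weighted time constant
    ``tau_w = tau_fast * %A_fast + tau_slow * (1 - %A_fast)`` with
    ``%A_fast = A_fast / (A_fast + A_slow)``.  If the double fit fails to
    converge or its two time constants are indistinguishable, the single fit
    is returned with a warning.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size:
        raise InvalidParameterError("t and y must have the same length")
    if t.size < 20:
        raise InsufficientDataError("decay fit needs at least 20 samples")
    if model not in ("single", "double"):
        raise InvalidParameterError(f"model must be 'single' or 'double', got {model!r}")

    peak = y[0]
    if peak == 0:
        raise DegenerateInputError("trace starts at zero; no decay to fit")
    span = t[-1] - t[0]
    tau0 = max(span / 5.0, 1e-3)

    def single(tt, a, tau):
        return a * np.exp(-tt / tau)

    def do_single() -> FitResult:
        popt, _ = curve_fit(single, t, y, p0=(peak, tau0), maxfev=20000)
        yhat = single(t, *popt)
        return FitResult(
            model="single_exp",
            params={"amplitude": float(popt[0]), "tau": float(abs(popt[1]))},
            r_squared=_r_squared(y, yhat),
        )

    if model == "single":
        return do_single()

    def double(tt, af, tf, as_, ts):
        return af * np.exp(-tt / tf) + as_ * np.exp(-tt / ts)

    try:
        popt, _ = curve_fit(
            double, t, y,
            p0=(0.8 * peak, tau0 / 4.0, 0.2 * peak, tau0 * 2.0),
            maxfev=20000,
        )
    except RuntimeError:
        warnings.warn("double-exponential fit did not converge; falling back to single",
                      stacklevel=2)
        return do_single()

    af, tf, as_, ts = popt
    tf, ts = abs(tf), abs(ts)
    if tf > ts:  # order components fast-first
        af, as_, tf, ts = as_, af, ts, tf
    if ts / max(tf, 1e-12) < 1.2:
        warnings.warn("double-exponential components are ill-conditioned "
                      "(tau_fast ~ tau_slow); falling back to single", stacklevel=2)
        return do_single()
    total = af + as_
    if total == 0:
        raise FitFailureError("component amplitudes cancel; %A_fast undefined")
    pct_fast = af / total
    tau_w = tf * pct_fast + ts * (1.0 - pct_fast)
    yhat = double(t, af, tf, as_, ts)
    return FitResult(
        model="double_exp",
        params={
            "a_fast": float(af), "tau_fast": float(tf),
            "a_slow": float(as_), "tau_slow": float(ts),
            "pct_a_fast": float(pct_fast),
        },
        r_squared=_r_squared(y, yhat),
        tau_weighted=float(tau_w),
    )


def fi_slope(
    currents: Sequence[float],
    rates: Sequence[float],
    force_zero_intercept: bool = False,
) -> FitResult:
    """Linear fit of firing rate (Hz) vs injected current (pA)."""
    x = np.asarray(currents, dtype=float)
    y = np.asarray(rates, dtype=float)
    if x.size != y.size:
        raise InvalidParameterError("currents and rates must match in length")
    if force_zero_intercept:
        if x.size < 1 or np.all(x == 0):
            raise DegenerateInputError("cannot fit a slope through the origin: no leverage")
        slope = float(np.sum(x * y) / np.sum(x * x))
        intercept = 0.0
    else:
        if x.size < 3:
            raise InsufficientDataError("free-intercept f-I fit needs at least 3 points")
        if np.ptp(x) == 0:
            raise DegenerateInputError("degenerate currents: all equal")
        slope_, icpt_ = np.polyfit(x, y, 1)
        slope, intercept = float(slope_), float(icpt_)
    yhat = slope * x + intercept
    return FitResult(
        model="linear",
        params={"slope": slope, "intercept": intercept},
        r_squared=_r_squared(y, yhat),
    )


def mean_instantaneous_rate(spike_times: Sequence[float]) -> float:
    """Mean of reciprocal inter-spike intervals, in Hz (times in ms)."""
    isis = np.diff(np.asarray(spike_times, dtype=float))
    if isis.size == 0:
        raise InsufficientDataError("need at least 2 spikes for an instantaneous rate")
    return float(np.mean(1000.0 / isis))


def adaptation_ratio(
    spike_times: Sequence[float],
    initial_spikes: tuple[int, int] = (5, 10),
) -> float:
    """Steady-state over initial instantaneous firing rate within a step.

    Initial = mean instantaneous rate over spikes #5-10 (1-based,
    configurable); steady state = over the last five spikes.  Requires at
    least 15 spikes; responses below that are excluded from analysis.
    """
    times = np.asarray(spike_times, dtype=float)
    if times.size < MIN_SPIKES_FOR_ADAPTATION:
        raise InsufficientDataError(
            f"adaptation ratio needs >= {MIN_SPIKES_FOR_ADAPTATION} spikes, got {times.size}"
        )
    a, b = initial_spikes
    if not 1 <= a < b <= times.size:
        raise InvalidParameterError("invalid initial-spike window")
    isis = np.diff(times)
    initial = isis[a - 1 : b - 1]
    steady = isis[-4:]
    return float(np.mean(1000.0 / steady) / np.mean(1000.0 / initial))


def firing_sensitivity(
    n_inputs: Sequence[float], spike_counts: Sequence[float]
) -> FitResult:
    """Slope of spikes-per-trial versus number of simulated inputs."""
    x = np.asarray(n_inputs, dtype=float)
    y = np.asarray(spike_counts, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("firing sensitivity needs >= 3 (inputs, count) pairs")
    if np.ptp(x) == 0:
        raise DegenerateInputError("degenerate input counts: all equal")
    return fi_slope(x, y, force_zero_intercept=False)


def first_spike_latency(spike_times: Sequence[float]) -> float | None:
    """Time (ms) of the first spike, or None if the trial failed to spike."""
    times = np.asarray(spike_times, dtype=float)
    return float(times[0]) if times.size else None


def detect_spikes(
    v: Sequence[float], dt: float, level: float = -20.0
) -> np.ndarray:
    """Spike peak times from a voltage trace by upward level crossing."""
    v = np.asarray(v, dtype=float)
    above = v >= level
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    peaks = []
    for i in onsets:
        j = i
        while j + 1 < v.size and above[j + 1]:
            j += 1
        peaks.append(i + int(np.argmax(v[i : j + 1])))
    return np.asarray(peaks, dtype=float) * dt


def iei_histogram_fit(
    events: EventSet | Sequence[float],
    bin_width: float = 0.02,
    method: str = "least_squares",
) -> FitResult:
    """Fit a single exponential to the binned inter-event-interval histogram.

    ``bin_width`` is in seconds (default 0.02 s = 20 ms bins); event times in
    an :class:`EventSet` are in ms and converted.  Returns tau in seconds.
    ``method='mle'`` instead returns the maximum-likelihood estimate (the
    sample mean) for cross-checking; least squares on counts is the default.
    """
    if isinstance(events, EventSet):
        ieis = events.ieis / 1000.0  # s
    else:
        ieis = np.asarray(events, dtype=float)
    if ieis.size < 100:
        raise InsufficientDataError("IEI fit needs at least 100 events")
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be positive")

    if method == "mle":
        tau = float(ieis.mean())
        return FitResult(model="single_exp", params={"tau": tau, "amplitude": None},
                         r_squared=1.0)
    if method != "least_squares":
        raise InvalidParameterError(f"unknown method {method!r}")

    edges = np.arange(0.0, ieis.max() + bin_width, bin_width)
    counts, edges = np.histogram(ieis, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def model(t, a, tau):
        return a * np.exp(-t / tau)

    p0 = (float(counts.max()), float(max(ieis.mean(), bin_width)))
    try:
        popt, _ = curve_fit(
            model, centers, counts, p0=p0,
            bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"IEI histogram fit did not converge: {exc}") from exc
    a, tau = popt
    yhat = model(centers, a, tau)
    return FitResult(
        model="single_exp",
        params={"tau": float(abs(tau)), "amplitude": float(a)},
        r_squared=_r_squared(counts.astype(float), yhat),
    )


@dataclass(frozen=True)
class AmplitudeSummary:
    mean: float
    median: float
    minimum: float
    maximum: float
    n: int
    bin_edges: np.ndarray
    counts: np.ndarray


def amplitude_stats(events: EventSet, bin_width: float = 1.5) -> AmplitudeSummary:
    """Descriptive statistics and a binned histogram of event amplitudes (pA).

    Bins are anchored at zero with the given width (default 1.5 pA), so the
    histogram is bit-reproducible for a given bin width.
    """
    amps = events.amplitudes
    if amps.size == 0:
        raise InsufficientDataError("no events")
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be positive")
    hi = (np.floor(amps.max() / bin_width) + 1) * bin_width
    edges = np.arange(0.0, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(amps, bins=edges)
    return AmplitudeSummary(
        mean=float(amps.mean()),
        median=float(np.median(amps)),
        minimum=float(amps.min()),
        maximum=float(amps.max()),
        n=int(amps.size),
        bin_edges=edges,
        counts=counts,
    )
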