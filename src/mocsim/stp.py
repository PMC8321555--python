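"""Per-pulse short-term plasticity weights, plasticity index and recovery.

Two opposing forms of short-term plasticity are modelled phenomenologically,
as fitted to normalized EPSC amplitudes during 20-pulse tetani:

* facilitation (descending, inferior-colliculus-like input)::

      w(0) = 1,   w(n) = Fac_max + A * exp(-n / tau),        n >= 1

* depression (ascending, cochlear-nucleus-like input)::

      w(0) = 1,   w(n) = Dep_max + A1 * exp(-n / tau1)
                                 + A2 * exp(-n / tau2),      n >= 1

with ``n`` the pulse index.  The weights are a function of pulse index only
(frequency-invariant); time constants are in pulse-index units.  Recovery of
the end-of-train state back to baseline after a tetanus follows a single
exponential with a time constant of a few seconds, so within-train recovery
is neglected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DegenerateInputError,
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "FacilitationParams",
    "DepressionParams",
    "RecoveryParams",
    "PlasticityParams",
    "weight",
    "weight_sequence",
    "plasticity_index",
    "recovery_amplitude",
    "fit_recovery",
    "fit_weights",
    "RecoveryFit",
]


@dataclass(frozen=True)
class FacilitationParams:
    """Facilitation weight-function parameters (pulse-index units)."""

    fac_max: float = 2.43
    amplitude: float = -1.42
    tau: float = 12.9

    def __post_init__(self) -> None:
        if self.fac_max <= 1:
            raise InvalidParameterError("fac_max must exceed 1 for a facilitating synapse")
        if self.tau <= 0:
            raise InvalidParameterError("tau must be positive")

    def __call__(self, n: np.ndarray | float) -> np.ndarray | float:
        return self.fac_max + self.amplitude * np.exp(-np.asarray(n, float) / self.tau)


@dataclass(frozen=True)
class DepressionParams:
    """Depression weight-function parameters (pulse-index units)."""

    dep_max: float = 0.309
    a1: float = 0.443
    tau1: float = 0.771
    a2: float = 0.248
    tau2: float = 4.10

    def __post_init__(self) -> None:
        if not 0 < self.dep_max < 1:
            raise InvalidParameterError("dep_max must lie in (0, 1)")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise InvalidParameterError("time constants must be positive")

    def __call__(self, n: np.ndarray | float) -> np.ndarray | float:
        n = np.asarray(n, float)
        return (
            self.dep_max
            + self.a1 * np.exp(-n / self.tau1)
            + self.a2 * np.exp(-n / self.tau2)
        )


PlasticityParams = Union[FacilitationParams, DepressionParams]

#: Post-tetanus recovery time constants (s), from 20-Hz tetanus fits.
DEPRESSION_RECOVERY_TAU = 3.5
FACILITATION_RECOVERY_TAU = 4.5


@dataclass(frozen=True)
class RecoveryParams:
    """Single-exponential recovery of synaptic state after a tetanus."""

    tau_recovery: float  # s
    baseline: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_recovery <= 0:
            raise InvalidParameterError("tau_recovery must be positive")

    @classmethod
    def depressing(cls) -> "RecoveryParams":
        return cls(DEPRESSION_RECOVERY_TAU)

    @classmethod
    def facilitating(cls) -> "RecoveryParams":
        return cls(FACILITATION_RECOVERY_TAU)


def weight(n: int, params: PlasticityParams) -> float:
    """Synaptic weight of pulse ``n`` (0-based).  The first pulse is exactly 1."""
    if n < 0 or int(n) != n:
        raise InvalidParameterError(f"pulse index must be a non-negative integer, got {n}")
    if n == 0:
        return 1.0
    return float(params(n))


def weight_sequence(n_pulses: int, params: PlasticityParams) -> np.ndarray:
    """Weights for pulse indices ``0 .. n_pulses - 1``."""
    if n_pulses < 1:
        raise InvalidParameterError("n_pulses must be >= 1")
    w = np.asarray(params(np.arange(n_pulses, dtype=float)), dtype=float)
    w[0] = 1.0
    return w


def plasticity_index(amplitudes: Sequence[float], kind: str) -> float:
    """Ratio quantifying facilitation or depression over a tetanus.

    ``depressing``: mean of the last three amplitudes over the first
    amplitude.  ``facilitating``: mean of the last three over the mean of the
    first three.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size < 4:
        raise InsufficientDataError("plasticity index needs at least 4 amplitudes")
    last = amps[-3:].mean()
    if kind == "depressing":
        denom = amps[0]
    elif kind == "facilitating":
        denom = amps[:3].mean()
    else:
        raise InvalidParameterError(f"kind must be 'facilitating' or 'depressing', got {kind!r}")
    if denom == 0:
        raise DegenerateInputError("zero denominator in plasticity index")
    return float(last / denom)


def recovery_amplitude(
    dt_after_tetanus: float, end_state: float, params: RecoveryParams
) -> float:
    """Relative test-pulse amplitude ``dt`` seconds after a tetanus.

    ``baseline + (end_state - baseline) * exp(-dt / tau_recovery)``: equals
    the end-of-train state at ``dt = 0`` and returns to baseline as
    ``dt -> inf``.
    """
    if dt_after_tetanus < 0:
        raise InvalidParameterError("dt_after_tetanus must be >= 0")
    b = params.baseline
    return float(b + (end_state - b) * math.exp(-dt_after_tetanus / params.tau_recovery))


@dataclass(frozen=True)
class RecoveryFit:
    tau_recovery: float  # s
    end_state: float
    residual: float  # RMS of fit residuals


def fit_recovery(dts: Sequence[float], amplitudes: Sequence[float]) -> RecoveryFit:
    """Least-squares single-exponential fit of post-tetanus recovery.

    Fits ``a(dt) = 1 + (e0 - 1) * exp(-dt / tau)`` for the end state ``e0``
    and recovery time constant ``tau`` (seconds).
    """
    dts = np.asarray(dts, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if dts.size != amps.size:
        raise InvalidParameterError("dts and amplitudes must have equal length")
    if dts.size < 4:
        raise InsufficientDataError("recovery fit needs at least 4 points")
    if np.any(dts <= 0) or dts.max() / dts.min() < 10:
        raise InvalidParameterError("dts must be positive and span at least one decade")
    if np.allclose(amps, amps[0], rtol=1e-10, atol=1e-12):
        raise FitFailureError("recovery amplitudes are constant; tau is unidentifiable")

    def model(dt, tau, e0):
        return 1.0 + (e0 - 1.0) * np.exp(-dt / tau)

    p0 = (max(np.median(dts), 1e-3), amps[0])
    try:
        popt, _ = curve_fit(model, dts, amps, p0=p0, maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitFailureError(f"recovery fit did not converge: {exc}") from exc
    tau, e0 = popt
    if tau <= 0:
        raise FitFailureError(f"recovery fit produced non-positive tau ({tau:g} s)")
    resid = float(np.sqrt(np.mean((model(dts, *popt) - amps) ** 2)))
    return RecoveryFit(tau_recovery=float(tau), end_state=float(e0), residual=resid)


def fit_weights(amplitudes: Sequence[float], kind: str) -> PlasticityParams:
    """Fit the facilitation or depression weight function to amplitudes.

    Amplitudes are first normalized to the first pulse; pulse 0 is excluded
    from the fit (its weight is fixed at 1 by construction).
    """
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size < 6:
        raise InsufficientDataError("weight-function fit needs at least 6 pulses")
    if amps[0] == 0:
        raise DegenerateInputError("first amplitude is zero; cannot normalize")
    w = amps / amps[0]
    n = np.arange(1, w.size, dtype=float)
    y = w[1:]
    if kind == "facilitating":
        def model(n, fmax, a, tau):
            return fmax + a * np.exp(-n / tau)

        popt, _ = curve_fit(
            model, n, y, p0=(max(y.max(), 1.1), 1.0 - max(y.max(), 1.1), 10.0),
            maxfev=20000,
        )
        return FacilitationParams(*popt)
    if kind == "depressing":
        def model(n, dmax, a1, tau1, a2, tau2):
            # clip exponents: the optimizer may probe tiny tau values
            with np.errstate(over="ignore"):
                return (dmax + a1 * np.exp(-np.minimum(n / tau1, 700.0))
                        + a2 * np.exp(-np.minimum(n / tau2, 700.0)))

        dmax0 = float(np.clip(y.min(), 0.05, 0.95))
        popt, _ = curve_fit(
            model, n, y, p0=(dmax0, 0.5, 1.0, 0.2, 5.0), maxfev=20000,
        )
        return DepressionParams(*popt)
    raise InvalidParameterError(f"kind must be 'facilitating' or 'depressing', got {kind!r}")
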