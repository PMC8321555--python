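"""Tonic presynaptic spike-train generation.

The conductance-clamp experiments drive the model neuron with ensembles of
tonically firing presynaptic inputs patterned after T-stellate "sustained
chopper" activity: regular inter-spike intervals with modest jitter, repeated
over 80 independent 500-ms trials per rate paradigm.  Three ensemble rate
paradigms are used throughout: ``low`` (~41 Hz), ``mid`` (~111 Hz) and
``high`` (~176 Hz).

Because only ensemble mean rates (and their standard errors) are published,
the inter-spike-interval statistics are a modelling choice: intervals are
jittered-regular (base interval ``1/rate`` with multiplicative Gaussian
jitter of coefficient of variation ``isi_cv``, floored at an absolute
refractory period), not Poisson.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import EmptyInputError, InvalidParameterError

__all__ = [
    "SpikeTrain",
    "TrainEnsemble",
    "PARADIGM_RATES",
    "PARADIGM_SEMS",
    "generate_tonic_train",
    "generate_paradigm",
    "ensemble_mean_rate",
    "ensemble_to_tsv",
    "ensemble_from_tsv",
    "ensemble_to_json",
    "ensemble_from_json",
]

#: Ensemble target mean rate (Hz) for each paradigm label.
PARADIGM_RATES = {"low": 41.1, "mid": 111.0, "high": 176.0}
#: Published standard error of the 80-trial ensemble mean (Hz).
PARADIGM_SEMS = {"low": 0.5, "mid": 1.0, "high": 1.0}

DEFAULT_DURATION = 500.0  # ms, one trial
DEFAULT_ISI_CV = 0.15
DEFAULT_REFRACTORY = 1.0  # ms
DEFAULT_N_TRIALS = 80


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered presynaptic event times for one input over one trial.

    Parameters
    ----------
    times
        Strictly increasing event times in ms, all within ``[0, duration)``.
    duration
        Trial length in ms.
    trial_id
        Index of the trial within its ensemble.
    """

    times: np.ndarray
    duration: float = DEFAULT_DURATION
    trial_id: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.duration <= 0:
            raise InvalidParameterError("duration must be positive")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise InvalidParameterError("spike times must be strictly increasing")
            if times[0] < 0 or times[-1] >= self.duration:
                raise InvalidParameterError("spike times must lie in [0, duration)")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Trial firing rate in Hz (count / duration)."""
        return self.n_spikes / self.duration * 1000.0


@dataclass(frozen=True)
class TrainEnsemble:
    """A set of spike trains, one per trial, sharing a rate paradigm."""

    trains: tuple[SpikeTrain, ...]
    paradigm_label: str = ""
    target_rate: float = float("nan")
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "trains", tuple(self.trains))

    def __len__(self) -> int:
        return len(self.trains)

    def __iter__(self):
        return iter(self.trains)

    @property
    def duration(self) -> float:
        if not self.trains:
            raise EmptyInputError("ensemble has no trains")
        return self.trains[0].duration


def _validate_rate_duration(mean_rate: float, duration: float) -> None:
    if mean_rate < 0:
        raise InvalidParameterError(f"mean_rate must be >= 0, got {mean_rate}")
    if duration <= 0:
        raise InvalidParameterError(f"duration must be > 0, got {duration}")


def generate_tonic_train(
    mean_rate: float,
    duration: float = DEFAULT_DURATION,
    isi_cv: float = DEFAULT_ISI_CV,
    refractory: float = DEFAULT_REFRACTORY,
    onset_jitter: float | None = None,
    seed: int | np.random.Generator | None = None,
    trial_id: int = 0,
) -> SpikeTrain:
    """Generate one jittered-regular tonic spike train.

    Intervals are ``(1000 / mean_rate) * max(1 + isi_cv * z, eps)`` with
    ``z ~ N(0, 1)``, floored at ``refractory``; the first spike latency is
    drawn uniformly in ``[0, onset_jitter]`` (default: one mean interval), so
    independently generated trains are desynchronized.

    Parameters
    ----------
    mean_rate
        Target firing rate in Hz.  Zero yields an empty train.
    duration
        Trial length in ms.
    isi_cv
        Coefficient of variation of the interval jitter, ``0 <= isi_cv < 1``.
    refractory
        Absolute refractory period in ms; no interval is shorter.
    onset_jitter
        Upper bound (ms) of the uniform first-spike latency.
    seed
        Integer seed or a ``numpy.random.Generator``.
    """
    _validate_rate_duration(mean_rate, duration)
    if not 0 <= isi_cv < 1:
        raise InvalidParameterError(f"isi_cv must be in [0, 1), got {isi_cv}")
    if refractory < 0:
        raise InvalidParameterError("refractory must be >= 0")
    if mean_rate == 0:
        return SpikeTrain(np.empty(0), duration=duration, trial_id=trial_id)

    rng = np.random.default_rng(seed)
    base_isi = 1000.0 / mean_rate  # ms
    if onset_jitter is None:
        onset_jitter = base_isi

    # Draw intervals in blocks until the trial is covered, then trim.
    n_draw = max(8, int(np.ceil(duration / base_isi * 1.5)) + 8)
    times: list[float] = [rng.uniform(0.0, onset_jitter)]
    while times[-1] < duration:
        isis = base_isi * (1.0 + isi_cv * rng.standard_normal(n_draw))
        np.maximum(isis, refractory, out=isis)
        times.extend((times[-1] + np.cumsum(isis)).tolist())
    arr = np.asarray(times)
    return SpikeTrain(arr[arr < duration], duration=duration, trial_id=trial_id)


def generate_paradigm(
    paradigm: str,
    n_trials: int = DEFAULT_N_TRIALS,
    duration: float = DEFAULT_DURATION,
    seed: int | None = None,
    isi_cv: float = DEFAULT_ISI_CV,
    refractory: float = DEFAULT_REFRACTORY,
) -> TrainEnsemble:
    """Generate an ensemble of trials for one rate paradigm.

    Per-trial target rates are drawn as Gaussians around the paradigm mean
    with a between-trial spread of ``SEM * sqrt(80)``, which reproduces the
    published standard errors of the 80-trial ensemble means
    (41.1 +/- 0.5, 111 +/- 1 and 176 +/- 1 Hz).
    """
    if paradigm not in PARADIGM_RATES:
        raise InvalidParameterError(
            f"unknown paradigm {paradigm!r}; expected one of {sorted(PARADIGM_RATES)}"
        )
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    target = PARADIGM_RATES[paradigm]
    spread = PARADIGM_SEMS[paradigm] * np.sqrt(DEFAULT_N_TRIALS)

    root = np.random.SeedSequence(seed)
    rate_rng = np.random.default_rng(root.spawn(1)[0])
    trial_rates = np.maximum(rate_rng.normal(target, spread, size=n_trials), 0.0)
    trains = [
        generate_tonic_train(
            r,
            duration=duration,
            isi_cv=isi_cv,
            refractory=refractory,
            seed=np.random.default_rng(ss),
            trial_id=i,
        )
        for i, (r, ss) in enumerate(zip(trial_rates, root.spawn(n_trials + 1)[1:]))
    ]
    return TrainEnsemble(tuple(trains), paradigm_label=paradigm, target_rate=target, seed=seed)


def ensemble_mean_rate(ensemble: TrainEnsemble | Iterable[SpikeTrain]) -> tuple[float, float]:
    """Mean and standard error of per-trial firing rates (Hz) over an ensemble."""
    trains = list(ensemble)
    if not trains:
        raise EmptyInputError("ensemble is empty")
    rates = np.array([t.rate for t in trains])
    mean = float(rates.mean())
    sem = float(rates.std(ddof=1) / np.sqrt(rates.size)) if rates.size > 1 else 0.0
    return mean, sem


# ---------------------------------------------------------------------------
# text / JSON interchange

def ensemble_to_tsv(ensemble: TrainEnsemble, path: str | Path) -> None:
    """Write an ensemble as two-column delimited text (trial_id, time_ms)."""
    with open(path, "w") as fh:
        fh.write("trial_id\ttime_ms\n")
        for train in ensemble:
            for t in train.times:
                fh.write(f"{train.trial_id}\t{t:.6f}\n")


def ensemble_from_tsv(
    path: str | Path, duration: float = DEFAULT_DURATION, paradigm_label: str = ""
) -> TrainEnsemble:
    data = np.loadtxt(path, skiprows=1, ndmin=2)
    trains = []
    if data.size:
        ids = data[:, 0].astype(int)
        for tid in np.unique(ids):
            times = np.sort(data[ids == tid, 1])
            trains.append(SpikeTrain(times, duration=duration, trial_id=int(tid)))
    return TrainEnsemble(tuple(trains), paradigm_label=paradigm_label)


def ensemble_to_json(ensemble: TrainEnsemble, path: str | Path) -> None:
    payload = {
        "paradigm_label": ensemble.paradigm_label,
        "target_rate": None if np.isnan(ensemble.target_rate) else ensemble.target_rate,
        "seed": ensemble.seed,
        "duration": ensemble.duration if len(ensemble) else DEFAULT_DURATION,
        "trains": [
            {"trial_id": t.trial_id, "times": t.times.tolist()} for t in ensemble
        ],
    }
    Path(path).write_text(json.dumps(payload))


def ensemble_from_json(path: str | Path) -> TrainEnsemble:
    payload = json.loads(Path(path).read_text())
    duration = payload.get("duration", DEFAULT_DURATION)
    trains = tuple(
        SpikeTrain(np.asarray(t["times"]), duration=duration, trial_id=t["trial_id"])
        for t in payload["trains"]
    )
    return TrainEnsemble(
        trains,
        paradigm_label=payload.get("paradigm_label", ""),
        target_rate=payload.get("target_rate") or float("nan"),
        seed=payload.get("seed"),
    )
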