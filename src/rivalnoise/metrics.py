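"""Percept-timecourse analysis.

All analyses here apply identically to simulated percepts and to
button-press-style human reports: epoch extraction, dominance-duration
statistics, double-pass consistency, autocorrelation of the percept, and
cross-correlation between the percept and the interocular contrast
difference.

Percepts are coded per sample as LEFT = +1, RIGHT = -1, TIE = 0.  TIEs
(mixed percepts) are excluded from consistency, and retained as 0 in the
correlation analyses.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .noise import NoiseStream

__all__ = [
    "LEFT",
    "RIGHT",
    "TIE",
    "PerceptTimecourse",
    "Epoch",
    "EpochList",
    "CorrelationFunction",
    "ConditionSummary",
    "extract_epochs",
    "duration_stats",
    "consistency",
    "autocorrelation",
    "crosscorrelation",
    "DEFAULT_BINS",
]

LEFT, RIGHT, TIE = 1, -1, 0

#: 30 log-spaced histogram bins over [0.1, 30] s, matching the logarithmic
#: presentation of dominance-duration histograms in the rivalry literature.
DEFAULT_BINS = np.geomspace(0.1, 30.0, 31)


@dataclass(frozen=True)
class PerceptTimecourse:
    """Uniform-grid sequence of percept labels {+1, -1, 0}."""

    labels: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        if labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if not np.isin(labels, (LEFT, RIGHT, TIE)).all():
            raise ValueError("labels must be coded LEFT=+1, RIGHT=-1, TIE=0")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValueError("dt must be finite and positive")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    def crop(self, t_start: float = 0.0, t_stop: Optional[float] = None) -> "PerceptTimecourse":
        """Sub-timecourse on [t_start, t_stop); used to drop onset transients."""
        i0 = int(np.ceil(t_start / self.dt - 1e-12))
        i1 = self.n if t_stop is None else int(np.floor(t_stop / self.dt + 1e-12))
        return PerceptTimecourse(self.labels[i0:i1], self.dt)

    def to_file(self, path: str) -> None:
        data = np.column_stack([self.times, self.labels])
        tmp = path + ".tmp"
        np.savetxt(tmp, data, fmt=["%.6f", "%d"], delimiter="\t", header="time_s\tlabel")
        os.replace(tmp, path)

    @classmethod
    def from_file(cls, path: str) -> "PerceptTimecourse":
        data = np.loadtxt(path, delimiter="\t")
        dt = float(np.median(np.diff(data[:, 0])))
        return cls(data[:, 1].astype(np.int8), dt)


@dataclass(frozen=True)
class Epoch:
    label: int
    start: float
    duration: float
    censored: bool = False  # touches a boundary of the analysed interval


@dataclass(frozen=True)
class EpochList:
    """Ordered dominance epochs tiling the analysed interval."""

    epochs: Tuple[Epoch, ...]

    def __iter__(self):
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def complete(self) -> Tuple[Epoch, ...]:
        """Epochs not touching either end of the record (usable for stats)."""
        return tuple(e for e in self.epochs if not e.censored)

    @property
    def complete_durations(self) -> np.ndarray:
        return np.array([e.duration for e in self.complete])


@dataclass(frozen=True)
class CorrelationFunction:
    """Pearson correlation per lag, with the location of the peak.

    Negative lags mean the percept trails the reference signal (the response
    follows the stimulus after a delay).
    """

    lags: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lags", np.asarray(self.lags, dtype=float))
        object.__setattr__(self, "coefficients", np.asarray(self.coefficients, dtype=float))
        if self.lags.shape != self.coefficients.shape:
            raise ValueError("lags and coefficients must have the same shape")

    @property
    def peak_index(self) -> int:
        finite = np.where(np.isfinite(self.coefficients), self.coefficients, -np.inf)
        return int(np.argmax(finite))

    @property
    def peak_lag(self) -> float:
        return float(self.lags[self.peak_index])

    @property
    def peak_r(self) -> float:
        return float(self.coefficients[self.peak_index])

    def to_file(self, path: str) -> None:
        data = np.column_stack([self.lags, self.coefficients])
        tmp = path + ".tmp"
        np.savetxt(tmp, data, fmt="%.9g", delimiter="\t", header="lag_s\tr")
        os.replace(tmp, path)


@dataclass
class ConditionSummary:
    """Per-condition aggregates over repetitions of a double-pass simulation."""

    condition: str
    mean_duration: Optional[float]
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    mean_consistency: Optional[float]
    n_trials: int
    n_epochs: int = 0
    sem_duration: Optional[float] = None
    sem_consistency: Optional[float] = None
    autocorr: Optional[CorrelationFunction] = None
    crosscorr: Optional[CorrelationFunction] = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "condition": self.condition,
            "mean_duration": self.mean_duration,
            "hist_edges": list(map(float, self.hist_edges)),
            "hist_counts": list(map(int, self.hist_counts)),
            "mean_consistency": self.mean_consistency,
            "n_trials": self.n_trials,
            "n_epochs": self.n_epochs,
            "sem_duration": self.sem_duration,
            "sem_consistency": self.sem_consistency,
            "extras": self.extras,
        }
        tmp = path + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        os.replace(tmp, path)


# ---------------------------------------------------------------------------
# epoch extraction


def extract_epochs(p: PerceptTimecourse, tie_policy: str = "absorb") -> EpochList:
    """Segment a percept timecourse into maximal constant-label epochs.

    TIE runs are handled by ``tie_policy``:

    * ``"absorb"`` (default): a TIE run is merged into the preceding labelled
      epoch, mirroring the convention of not analysing mixed percepts as
      events in their own right.  Leading TIEs join the first labelled epoch.
    * ``"separate"``: TIE runs become epochs of their own.

    The first and last epochs touch the record boundaries and are flagged
    censored; an all-TIE record yields an empty list.
    """
    if tie_policy not in ("absorb", "separate"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    labels = p.labels
    n = labels.shape[0]
    if n == 0:
        return EpochList(())

    if tie_policy == "absorb":
        work = labels.copy()
        # forward-fill over TIE samples, then back-fill a leading TIE run
        nz = work != TIE
        if not nz.any():
            return EpochList(())
        idx = np.where(nz, np.arange(n), 0)
        np.maximum.accumulate(idx, out=idx)
        work = work[idx]
        first = np.argmax(nz)
        work[:first] = work[first]
    else:
        work = labels

    change = np.flatnonzero(np.diff(work)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [n]])
    epochs = []
    for i, (a, b) in enumerate(zip(starts, stops)):
        censored = (i == 0) or (i == len(starts) - 1)
        epochs.append(
            Epoch(
                label=int(work[a]),
                start=float(a * p.dt),
                duration=float((b - a) * p.dt),
                censored=censored,
            )
        )
    return EpochList(tuple(epochs))


def duration_stats(
    epochs: EpochList, bins: Optional[Sequence[float]] = None
) -> Tuple[Optional[float], np.ndarray, np.ndarray]:
    """Mean dominance duration plus a histogram of complete epochs.

    Returns ``(mean, edges, counts)``.  Durations outside the bin range are
    clipped into the outer bins so the counts always sum to the number of
    complete epochs.  With no complete epoch the mean is ``None`` and a
    warning is issued.
    """
    edges = np.asarray(DEFAULT_BINS if bins is None else bins, dtype=float)
    durations = epochs.complete_durations
    if durations.size == 0:
        warnings.warn("no complete dominance epochs; duration statistics unavailable")
        return None, edges, np.zeros(edges.size - 1, dtype=int)
    clipped = np.clip(durations, edges[0], edges[-1] * (1 - 1e-12))
    counts, _ = np.histogram(clipped, edges)
    return float(durations.mean()), edges, counts


# ---------------------------------------------------------------------------
# double-pass consistency


def consistency(p1: PerceptTimecourse, p2: PerceptTimecourse) -> Optional[float]:
    """Fraction of jointly non-TIE samples with the same label across passes.

    Symmetric in its arguments; chance level is 0.5 for unbiased independent
    percepts.  Returns ``None`` when no sample is non-TIE in both passes.
    """
    if p1.n != p2.n or abs(p1.dt - p2.dt) > 1e-12:
        raise ValueError("the two percept timecourses must share the same grid")
    a, b = p1.labels, p2.labels
    both = (a != TIE) & (b != TIE)
    m = int(both.sum())
    if m == 0:
        return None
    return float(np.count_nonzero(a[both] == b[both]) / m)


# ---------------------------------------------------------------------------
# correlation functions


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _lagged_corr(x: np.ndarray, y: np.ndarray, max_lag_samples: int) -> Tuple[np.ndarray, np.ndarray]:
    """Pearson r of x[t] against y[t + lag] over the overlapping region."""
    lags = np.arange(-max_lag_samples, max_lag_samples + 1)
    coeffs = np.empty(lags.shape[0])
    for i, lag in enumerate(lags):
        if lag >= 0:
            xs, ys = x[: x.size - lag] if lag else x, y[lag:]
        else:
            xs, ys = x[-lag:], y[: y.size + lag]
        coeffs[i] = _pearson(xs, ys)
    return lags, coeffs


def autocorrelation(p: PerceptTimecourse, max_lag: float) -> CorrelationFunction:
    """Autocorrelation of the +/-1-coded percept over +/- ``max_lag`` seconds.

    Each lag's coefficient is a Pearson correlation over the overlapping
    region of the sequence with its shifted copy.
    """
    if max_lag >= p.duration / 2:
        raise ValueError("max_lag must be below half the timecourse duration")
    x = p.labels.astype(float)
    max_samples = int(round(max_lag / p.dt))
    lags, coeffs = _lagged_corr(x, x, max_samples)
    return CorrelationFunction(lags * p.dt, coeffs)


def crosscorrelation(
    p: PerceptTimecourse, noise_diff: NoiseStream, max_lag: float
) -> CorrelationFunction:
    """Cross-correlation between the percept and the (left - right) contrast difference.

    The noise stream is resampled to the percept grid by zero-order hold.
    Negative peak lags mean the percept trails the stimulus.
    """
    d = noise_diff.value_at(p.times)
    x = p.labels.astype(float)
    max_samples = int(round(max_lag / p.dt))
    lags, coeffs = _lagged_corr(x, d, max_samples)
    return CorrelationFunction(lags * p.dt, coeffs)
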