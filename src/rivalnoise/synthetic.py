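"""Synthetic observers for testing the analysis stages.

Human rivalry reports have a characteristic structure: alternating dominance
epochs whose durations are positively skewed and well approximated by a
gamma distribution, with occasional mixed percepts (about 3.2% of samples in
the experiment this package models).  :func:`generate_renewal_percepts`
emulates exactly that structure as an alternating renewal process, so every
metric and pipeline stage can be exercised without the ODE model or any
downloaded data.

What this generator deliberately does not emulate: serial correlations
between successive epoch durations, stimulus-driven entrainment, response
lags, or per-observer biases.  Stimulus coupling with a known lag is
provided separately by :func:`generate_stimulus_locked_percepts`.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import dataclass

import numpy as np

from .metrics import LEFT, RIGHT, TIE, PerceptTimecourse
from .noise import NoiseStream

__all__ = [
    "RenewalSpec",
    "generate_renewal_percepts",
    "generate_stimulus_locked_percepts",
    "load_human_summary",
]


@dataclass(frozen=True)
class RenewalSpec:
    """Alternating-renewal observer with gamma-distributed epoch durations.

    The defaults (shape 4, scale 0.675 s) give a mean dominance duration of
    2.7 s -- the published group mean -- with a shape value typical of the
    rivalry literature.  ``mix_prob`` inserts i.i.d. TIE samples at the
    published mixed-percept rate.
    """

    shape: float = 4.0
    scale: float = 0.675
    duration: float = 60.0
    dt: float = 0.01
    mix_prob: float = 0.032
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")
        if not 0 <= self.mix_prob < 1:
            raise ValueError("mix_prob must lie in [0, 1)")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")


def generate_renewal_percepts(spec: RenewalSpec) -> PerceptTimecourse:
    """Alternating LEFT/RIGHT epochs with i.i.d. gamma durations.

    Deterministic given the seed.  Warns (but still generates) when the
    requested duration is shorter than one expected epoch.
    """
    mean_epoch = spec.shape * spec.scale
    if spec.duration < mean_epoch:
        warnings.warn(
            f"duration {spec.duration:.3g}s is below one expected epoch ({mean_epoch:.3g}s)"
        )
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration / spec.dt))
    labels = np.empty(n, dtype=np.int8)
    # draw epochs until the trial is tiled
    current = LEFT if rng.integers(2) == 0 else RIGHT
    i = 0
    while i < n:
        d = rng.gamma(spec.shape, spec.scale)
        m = max(1, int(round(d / spec.dt)))
        labels[i : i + m] = current
        current = RIGHT if current == LEFT else LEFT
        i += m
    if spec.mix_prob > 0:
        ties = rng.random(n) < spec.mix_prob
        labels[ties] = TIE
    return PerceptTimecourse(labels, spec.dt)


def generate_stimulus_locked_percepts(
    noise_diff: NoiseStream,
    lag_s: float = 0.0,
    flip_prob: float = 0.0,
    dt: float = 0.01,
    seed: int = 0,
) -> PerceptTimecourse:
    """Percept = sign of the lagged interocular contrast difference.

    Constructs a percept with known stimulus coupling for cross-correlation
    tests: the label at time ``t`` follows ``noise_diff`` at ``t - lag_s``,
    with optional i.i.d. label flips at ``flip_prob`` per sample
    (``flip_prob = 0.5`` destroys the coupling entirely).
    """
    if lag_s < 0 or lag_s >= noise_diff.duration:
        raise ValueError("lag must be non-negative and within the stream")
    t = np.arange(0.0, noise_diff.duration, dt)
    src = np.clip(t - lag_s, 0.0, None)
    d = noise_diff.value_at(src)
    labels = np.where(d > 0, LEFT, np.where(d < 0, RIGHT, TIE)).astype(np.int8)
    if flip_prob > 0:
        rng = np.random.default_rng(seed)
        flips = rng.random(labels.shape[0]) < flip_prob
        labels[flips] = -labels[flips]
    return PerceptTimecourse(labels, dt)


def load_human_summary() -> dict:
    """The packaged published summary values, with per-cell provenance tags.

    Returns the raw nested dict; :class:`rivalnoise.pipeline.HumanSummary`
    offers a typed view over the same data.
    """
    resource = importlib.resources.files("rivalnoise.data").joinpath("human_summary.json")
    with resource.open("r") as fh:
        return json.load(fh)
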