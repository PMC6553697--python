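"""Stochastic input synthesis for rivalry experiments.

Two families of contrast-modulation streams are generated here, both as
zero-mean deviations (in % Michelson contrast) about a fixed 50% mean:

* **power-law internal noise** -- Fourier synthesis with amplitude
  coefficients proportional to ``f**-alpha`` and independent uniform random
  phases, rendered by an inverse real FFT.  ``alpha = 0`` is white noise,
  ``alpha = 1`` pink, ``alpha = 2`` a random-walk-like spectrum.
* **one-octave bandpass external noise** -- white Gaussian noise restricted
  in the frequency domain to the octave geometrically centred on a given
  frequency, i.e. the brick-wall passband ``[fc/sqrt(2), fc*sqrt(2)]``.

Every stream is demeaned and rescaled so its sample standard deviation
equals the requested SD exactly; this makes the nominal noise level of a
condition the realised level on every trial.  DC and Nyquist bins are zeroed
(the modulation is defined as a deviation about the mean contrast, and
``f**-alpha`` has no value at f = 0).

Streams are sampled on a uniform grid, 120 Hz by default to match a 120 Hz
display refresh.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "DEFAULT_DT",
    "NoiseStream",
    "PowerlawSpec",
    "BandpassSpec",
    "StimulusCondition",
    "StimulusMode",
    "make_powerlaw_noise",
    "make_powerlaw_pair",
    "make_bandpass_noise",
    "make_condition_streams",
    "write_stream",
    "read_stream",
]

#: default sample interval: one display frame at 120 Hz refresh.
DEFAULT_DT = 1.0 / 120.0

#: mean Michelson contrast of the rivalling gratings (%).
BASE_CONTRAST = 50.0


def _validate_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be finite and positive, got {value!r}")


def _validate_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value < 0:
            raise ValueError(f"{name} must be finite and non-negative, got {value!r}")


@dataclass(frozen=True)
class NoiseStream:
    """A sampled contrast-modulation signal on a uniform time grid.

    Parameters
    ----------
    samples
        Contrast deviations in % Michelson contrast, zero mean.
    dt
        Sample interval in seconds.
    meta
        Generator label, seed and spec parameters (free-form, serialised to
        the JSON sidecar on write).
    """

    samples: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        _validate_positive(dt=self.dt)

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Total stream length in seconds (n * dt)."""
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    def value_at(self, t: np.ndarray) -> np.ndarray:
        """Zero-order-hold evaluation at arbitrary times within the stream."""
        idx = np.minimum((np.asarray(t) / self.dt).astype(np.int64), self.n - 1)
        return self.samples[idx]


@dataclass(frozen=True)
class PowerlawSpec:
    """Specification of a 1/f^alpha noise stream."""

    alpha: float
    sd: float
    duration: float
    dt: float = DEFAULT_DT
    seed: int = 0

    def __post_init__(self) -> None:
        _validate_nonneg(alpha=self.alpha, sd=self.sd)
        _validate_positive(duration=self.duration, dt=self.dt)
        if self.duration < 2 * self.dt:
            raise ValueError("duration must cover at least two samples")


@dataclass(frozen=True)
class BandpassSpec:
    """Specification of a one-octave bandpass noise stream.

    The passband is ``[centre_freq/sqrt(2), centre_freq*sqrt(2)]``; the upper
    edge must stay below the Nyquist frequency of the sample grid.
    """

    centre_freq: float
    sd: float
    duration: float
    dt: float = DEFAULT_DT
    seed: int = 0

    def __post_init__(self) -> None:
        _validate_positive(centre_freq=self.centre_freq, duration=self.duration, dt=self.dt)
        _validate_nonneg(sd=self.sd)
        nyquist = 0.5 / self.dt
        if self.centre_freq * math.sqrt(2.0) >= nyquist:
            raise ValueError(
                f"upper passband edge {self.centre_freq * math.sqrt(2.0):.4g} Hz "
                f"reaches the Nyquist frequency {nyquist:.4g} Hz"
            )


class StimulusMode(str, Enum):
    """How the two eyes' contrast modulations relate to each other."""

    BASELINE = "BASELINE"          # no modulation at all
    INDEPENDENT = "INDEPENDENT"    # two independent bandpass streams
    ANTIPHASE = "ANTIPHASE"        # right stream is the exact negation of the left
    MONOCULAR = "MONOCULAR"        # two overlaid components in the same eye(s);
    # model input identical to INDEPENDENT, the tag is carried in stream meta


@dataclass(frozen=True)
class StimulusCondition:
    """One cell of the stimulus grid: a modulation mode plus its bandpass spec."""

    mode: StimulusMode
    bandpass: Optional[BandpassSpec] = None
    base_contrast: float = BASE_CONTRAST

    def __post_init__(self) -> None:
        if self.mode is StimulusMode.BASELINE:
            if self.bandpass is not None:
                raise ValueError("BASELINE condition takes no bandpass spec")
        elif self.bandpass is None:
            raise ValueError(f"{self.mode.value} condition requires a bandpass spec")

    @property
    def label(self) -> str:
        if self.bandpass is None:
            return "baseline"
        return f"{self.mode.value.lower()}_f{self.bandpass.centre_freq:g}_sd{self.bandpass.sd:g}"


# ---------------------------------------------------------------------------
# generators


def _grid(duration: float, dt: float) -> int:
    return int(round(duration / dt))


def _normalise(x: np.ndarray, sd: float) -> np.ndarray:
    x = x - x.mean()
    s = x.std()
    if s > 0 and sd > 0:
        x = x * (sd / s)
    elif sd == 0:
        x = np.zeros_like(x)
    return x


def _powerlaw_amplitude(n: int, dt: float, alpha: float) -> np.ndarray:
    """Deterministic amplitude profile f**-alpha over the rfft bins.

    DC is zero; for even n the Nyquist bin is zeroed as well so the stream is
    fully described by freely-phased components.
    """
    freqs = np.fft.rfftfreq(n, dt)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-alpha)
    if n % 2 == 0:
        amp[-1] = 0.0
    return amp


def make_powerlaw_noise(spec: PowerlawSpec) -> NoiseStream:
    """Generate one 1/f^alpha noise stream.

    Amplitude coefficients follow ``f**-alpha``; each component's phase is an
    independent uniform draw on (-pi, pi).  The rendered stream is demeaned
    and rescaled to ``spec.sd`` exactly.
    """
    n = _grid(spec.duration, spec.dt)
    amp = _powerlaw_amplitude(n, spec.dt, spec.alpha)
    rng = np.random.default_rng(spec.seed)
    phases = rng.uniform(-np.pi, np.pi, amp.shape[0])
    x = np.fft.irfft(amp * np.exp(1j * phases), n)
    x = _normalise(x, spec.sd)
    meta = {
        "generator": "powerlaw",
        "alpha": spec.alpha,
        "sd": spec.sd,
        "seed": spec.seed,
        "duration": spec.duration,
    }
    return NoiseStream(x, spec.dt, meta)


def make_powerlaw_pair(
    spec: PowerlawSpec, seed_left: int, seed_right: int
) -> Tuple[NoiseStream, NoiseStream]:
    """Two independent streams sharing the same deterministic amplitude profile.

    Only the phase spectra differ between the two streams, which is what makes
    them statistically independent while spectrally identical.
    """
    if seed_left == seed_right:
        raise ValueError("seed_left and seed_right must differ (equal seeds give identical streams)")
    left = make_powerlaw_noise(
        PowerlawSpec(spec.alpha, spec.sd, spec.duration, spec.dt, seed_left)
    )
    right = make_powerlaw_noise(
        PowerlawSpec(spec.alpha, spec.sd, spec.duration, spec.dt, seed_right)
    )
    return left, right


def make_bandpass_noise(spec: BandpassSpec) -> NoiseStream:
    """White noise restricted to one octave around ``spec.centre_freq``.

    The filter is a brick-wall frequency-domain mask over
    ``[fc/sqrt(2), fc*sqrt(2)]``: component phases inside the band are kept
    from the white-noise draw, everything outside (including DC) is zeroed.
    """
    n = _grid(spec.duration, spec.dt)
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, spec.dt)
    lo = spec.centre_freq / math.sqrt(2.0)
    hi = spec.centre_freq * math.sqrt(2.0)
    spectrum[(freqs < lo) | (freqs > hi)] = 0.0
    if not np.any((freqs >= lo) & (freqs <= hi)):
        raise ValueError(
            f"no Fourier bin falls in the passband [{lo:.4g}, {hi:.4g}] Hz; "
            f"increase duration (frequency resolution is {freqs[1]:.4g} Hz)"
        )
    x = np.fft.irfft(spectrum, n)
    x = _normalise(x, spec.sd)
    meta = {
        "generator": "bandpass",
        "centre_freq": spec.centre_freq,
        "sd": spec.sd,
        "seed": spec.seed,
        "duration": spec.duration,
    }
    return NoiseStream(x, spec.dt, meta)


def make_condition_streams(
    condition: StimulusCondition, seed: int, duration: Optional[float] = None, dt: Optional[float] = None
) -> Tuple[NoiseStream, NoiseStream]:
    """External modulation streams for the two eyes under a stimulus condition.

    BASELINE returns two all-zero streams; INDEPENDENT (and MONOCULAR, which
    differs only in what the two streams modulate, not in their statistics)
    returns two independent bandpass draws; ANTIPHASE returns one draw and its
    exact negation, so a contrast increment in one eye is matched by an equal
    decrement in the other.
    """
    if condition.mode is StimulusMode.BASELINE:
        duration = duration if duration is not None else 60.0
        dt = dt if dt is not None else DEFAULT_DT
        n = _grid(duration, dt)
        meta = {"generator": "baseline", "mode": "BASELINE", "seed": seed}
        zero = np.zeros(n)
        return NoiseStream(zero, dt, dict(meta)), NoiseStream(zero.copy(), dt, dict(meta))

    bp = condition.bandpass
    assert bp is not None
    if duration is not None or dt is not None:
        bp = BandpassSpec(
            bp.centre_freq,
            bp.sd,
            duration if duration is not None else bp.duration,
            dt if dt is not None else bp.dt,
            bp.seed,
        )

    from .seeds import child_seed

    if condition.mode is StimulusMode.ANTIPHASE:
        left = make_bandpass_noise(
            BandpassSpec(bp.centre_freq, bp.sd, bp.duration, bp.dt, child_seed(seed, 0))
        )
        right = NoiseStream(-left.samples, left.dt, {**left.meta, "antiphase_of": "left"})
    else:
        left = make_bandpass_noise(
            BandpassSpec(bp.centre_freq, bp.sd, bp.duration, bp.dt, child_seed(seed, 0))
        )
        right = make_bandpass_noise(
            BandpassSpec(bp.centre_freq, bp.sd, bp.duration, bp.dt, child_seed(seed, 1))
        )
    for s, eye in ((left, "left"), (right, "right")):
        s.meta["mode"] = condition.mode.value
        s.meta["eye_or_component"] = (
            f"component_{eye}" if condition.mode is StimulusMode.MONOCULAR else eye
        )
    return left, right


def clip_to_physical(stream: NoiseStream, base_contrast: float = BASE_CONTRAST) -> Tuple[np.ndarray, int]:
    """Stimulus contrast ``base + modulation`` clipped to the realisable [0, 100].

    Returns the clipped contrast timecourse and the number of clipped samples
    (rare for SD <= 16: excursions past 3 sigma).
    """
    contrast = base_contrast + stream.samples
    clipped = np.clip(contrast, 0.0, 100.0)
    return clipped, int(np.count_nonzero(clipped != contrast))


# ---------------------------------------------------------------------------
# plain-text serialisation: two-column TSV plus a JSON sidecar


def write_stream(stream: NoiseStream, path: str) -> None:
    """Write ``(time_s, contrast_pct)`` TSV with a ``<path>.json`` sidecar.

    Writes are atomic (temp file then rename).
    """
    data = np.column_stack([stream.times, stream.samples])
    tmp = path + ".tmp"
    np.savetxt(tmp, data, fmt="%.9g", delimiter="\t", header="time_s\tcontrast_pct")
    os.replace(tmp, path)
    sidecar = {"dt": stream.dt, "n": stream.n, "meta": stream.meta}
    tmp = path + ".json.tmp"
    with open(tmp, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    os.replace(tmp, path + ".json")


def read_stream(path: str) -> NoiseStream:
    data = np.loadtxt(path, delimiter="\t")
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    return NoiseStream(data[:, 1], float(sidecar["dt"]), sidecar.get("meta", {}))
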