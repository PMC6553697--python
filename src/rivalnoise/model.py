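"""The two-unit rivalry model: mutual inhibition, self-adaptation, gain control.

Each monocular unit's response :math:`E` obeys

.. math::

    \\tau \\dot E_L = -E_L + \\frac{M\\,[X_L]_+}{1 + [X_L]_+^{\\,p}},
    \\qquad
    X_L = L - \\omega E_R + \\varepsilon E_L - g H_L + N_L,

with the subscripts switched for the right-eye unit, and self-adaptation

.. math::

    \\tau_h \\dot H_L = -H_L + E_L.

:math:`[\\cdot]_+` is half-wave rectification, :math:`L` the stimulus
contrast delivered to the left eye, and :math:`N_L` additive internal noise.
Because noise and stimulus sum linearly inside the bracket, internal noise
is expressed in the same contrast units as the stimulus; the quotient places
the noise in both the numerator and the denominator of the gain control.

Contrast enters the drive on a *fraction* scale (50% Michelson -> 0.5): the
gain-control quotient has an implicit semi-saturation constant of 1, so a
mid-contrast stimulus must sit near the knee of the nonlinearity for the
inhibition loop gain to exceed 1 and relaxation oscillations (rivalry
alternations) to exist.  The public API still speaks % Michelson; the
conversion happens at the model boundary (``contrast_scale``).

Adaptation is suppressive (:math:`-gH`): :math:`H` tracks :math:`E`, so a
positive sign would be runaway self-excitation and the model would lock onto
one percept forever.  The opposing wiring remains selectable through
``adaptation_sign`` for comparison.

The dominant percept at any instant is simply the unit with the larger
response (winner take all); ties map to a TIE label.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from .metrics import LEFT, RIGHT, TIE, PerceptTimecourse
from .noise import NoiseStream

__all__ = [
    "Variant",
    "ModelParams",
    "ModelState",
    "TrialResult",
    "drive",
    "integrate_trial",
    "integrate_trial_fixed",
    "percept_from_responses",
    "apply_variant",
    "no_oscillator_percept",
    "READOUT_DT",
]

#: uniform readout grid for percept extraction and all metrics (100 Hz).
READOUT_DT = 0.01

#: default fixed integration step: divides both the 120 Hz noise frame and
#: the 100 Hz readout interval (600 = lcm(120, 100)).
FIXED_DT = 1.0 / 600.0


class Variant(str, Enum):
    """Model wirings explored alongside the main gain-control model."""

    MAIN = "MAIN"
    ADAPTATION_NOISE = "ADAPTATION_NOISE"  # internal noise moved to the H equation
    SHARED_NOISE = "SHARED_NOISE"          # one noise stream injected into both units
    LATE_NOISE = "LATE_NOISE"              # noise added after the gain-control quotient
    NO_OSCILLATOR = "NO_OSCILLATOR"        # memoryless comparator on noisy inputs


@dataclass(frozen=True)
class ModelParams:
    """All constants of the model plus the internal-noise specification.

    Defaults are the fixed values used throughout: self-excitation
    ``epsilon = 0.2``, inhibition ``omega = 3.5``, response gain ``M = 1.0``,
    adaptation strength ``g = 3.0``, excitatory time constant ``tau = 15 ms``,
    adaptation time constant ``tau_h = 4 s``, gain-control exponent
    ``p = 0.8``.  Internal noise defaults to pink (alpha = 1) at 16% contrast.
    """

    epsilon: float = 0.2
    omega: float = 3.5
    M: float = 1.0
    g: float = 3.0
    tau: float = 0.015
    tau_h: float = 4.0
    p: float = 0.8
    internal_alpha: float = 1.0
    internal_sd: float = 16.0
    variant: Variant = Variant.MAIN
    adaptation_sign: float = -1.0
    contrast_scale: float = 100.0
    init_perturb: float = 1e-6

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.tau_h <= 0:
            raise ValueError("time constants must be positive")
        if self.omega < 0 or self.g < 0:
            raise ValueError("omega and g must be non-negative")
        if self.internal_sd < 0 or self.internal_alpha < 0:
            raise ValueError("internal noise spec must be non-negative")
        object.__setattr__(self, "variant", Variant(self.variant))

    @property
    def noise_mode(self) -> int:
        if self.variant is Variant.ADAPTATION_NOISE:
            return _kernels.NOISE_IN_ADAPTATION
        if self.variant is Variant.LATE_NOISE:
            return _kernels.NOISE_LATE
        return _kernels.NOISE_IN_DRIVE

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["variant"] = self.variant.value
        return d


@dataclass(frozen=True)
class ModelState:
    """Instantaneous state of the four ODEs."""

    E_L: float
    E_R: float
    H_L: float
    H_R: float

    def as_array(self) -> np.ndarray:
        return np.array([self.E_L, self.E_R, self.H_L, self.H_R])


def drive(
    state: ModelState,
    inputs: dict,
    params: ModelParams,
) -> np.ndarray:
    """State derivative for instantaneous inputs ``{"L", "R", "N_L", "N_R"}`` (% contrast).

    This is the model right-hand side at a single instant, exposed for
    inspection and testing; the integrators below use the same wiring.
    Raises on non-finite state (integration blow-up signal).
    """
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"non-finite model state: {y}")
    s = params.contrast_scale
    L = inputs["L"] / s
    R = inputs["R"] / s
    NL = inputs.get("N_L", 0.0) / s
    NR = inputs.get("N_R", 0.0) / s
    if not np.all(np.isfinite([L, R, NL, NR])):
        raise ValueError("inputs must be finite")
    EL, ER, HL, HR = y
    XL = L - params.omega * ER + params.epsilon * EL + params.adaptation_sign * params.g * HL
    XR = R - params.omega * EL + params.epsilon * ER + params.adaptation_sign * params.g * HR
    mode = params.noise_mode
    if mode == _kernels.NOISE_IN_DRIVE:
        XL += NL
        XR += NR
    XL = max(XL, 0.0)
    XR = max(XR, 0.0)
    dEL = (-EL + params.M * XL / (1.0 + XL**params.p)) / params.tau
    dER = (-ER + params.M * XR / (1.0 + XR**params.p)) / params.tau
    if mode == _kernels.NOISE_LATE:
        dEL += NL / params.tau
        dER += NR / params.tau
    dHL = (-HL + EL) / params.tau_h
    dHR = (-HR + ER) / params.tau_h
    if mode == _kernels.NOISE_IN_ADAPTATION:
        dHL += NL / params.tau_h
        dHR += NR / params.tau_h
    return np.array([dEL, dER, dHL, dHR])


@dataclass
class TrialResult:
    """Readout-grid trajectories of one trial plus the streams that drove it."""

    t: np.ndarray
    E_L: np.ndarray
    E_R: np.ndarray
    H_L: np.ndarray
    H_R: np.ndarray
    params: ModelParams
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def percept(self) -> PerceptTimecourse:
        return percept_from_responses(self)

    def to_files(self, path: str) -> None:
        """Delimited trajectory table plus a JSON sidecar with params and meta."""
        labels = self.percept().labels
        data = np.column_stack([self.t, self.E_L, self.E_R, self.H_L, self.H_R, labels])
        tmp = path + ".tmp"
        np.savetxt(
            tmp,
            data,
            fmt="%.9g",
            delimiter="\t",
            header="time_s\tE_L\tE_R\tH_L\tH_R\tpercept",
        )
        os.replace(tmp, path)
        sidecar = {"params": self.params.to_dict(), "meta": self.meta}
        tmp = path + ".json.tmp"
        with open(tmp, "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True, default=str)
        os.replace(tmp, path + ".json")


def percept_from_responses(trial: TrialResult) -> PerceptTimecourse:
    """Winner-take-all readout: LEFT where E_L > E_R, RIGHT where E_R > E_L, TIE at equality."""
    labels = np.where(
        trial.E_L > trial.E_R, LEFT, np.where(trial.E_R > trial.E_L, RIGHT, TIE)
    ).astype(np.int8)
    return PerceptTimecourse(labels, trial.dt)


def apply_variant(
    params: ModelParams,
    internal_left: NoiseStream,
    internal_right: NoiseStream,
) -> Tuple[NoiseStream, NoiseStream]:
    """Resolve the internal-noise streams a variant actually consumes.

    SHARED_NOISE injects one stream into both units; every other variant uses
    the pair as given (the placement of the noise in the equations is wired
    by ``ModelParams.noise_mode``).  Unknown variants raise (guarded by the
    Variant enum at construction).
    """
    if params.variant is Variant.SHARED_NOISE:
        return internal_left, internal_left
    return internal_left, internal_right


def _check_streams(duration: float, *streams: NoiseStream) -> None:
    for s in streams:
        if s.duration < duration - 1e-9:
            raise ValueError(
                f"stream of duration {s.duration:.3f}s does not cover the {duration:.3f}s trial"
            )


def integrate_trial(
    params: ModelParams,
    external_left: NoiseStream,
    external_right: NoiseStream,
    internal_left: NoiseStream,
    internal_right: NoiseStream,
    duration: float = 60.0,
    rtol: float = 1e-6,
    readout_dt: float = READOUT_DT,
) -> TrialResult:
    """Adaptive-step reference integration of one trial.

    Uses :func:`scipy.integrate.solve_ivp` (RK45, ``rtol`` default 1e-6) with
    the maximum step capped at one noise frame so no zero-order-hold segment
    is skipped.  Trajectories are returned on the uniform readout grid with E
    floored at zero.
    """
    if params.variant is Variant.NO_OSCILLATOR:
        raise ValueError("NO_OSCILLATOR has no dynamics; use no_oscillator_percept")
    internal_left, internal_right = apply_variant(params, internal_left, internal_right)
    _check_streams(duration, external_left, external_right, internal_left, internal_right)

    s = params.contrast_scale
    base = 50.0 / s  # 50% Michelson mean contrast
    eL = external_left.samples / s
    eR = external_right.samples / s
    nL = internal_left.samples / s
    nR = internal_right.samples / s
    rate = 1.0 / internal_left.dt
    nn = nL.shape[0]
    eps, om, M, g, tau, tauh, p = (
        params.epsilon,
        params.omega,
        params.M,
        params.g,
        params.tau,
        params.tau_h,
        params.p,
    )
    sign = params.adaptation_sign
    mode = params.noise_mode

    def rhs(t: float, y: np.ndarray):
        if not (np.isfinite(y[0]) and np.isfinite(y[1]) and np.isfinite(y[2]) and np.isfinite(y[3])):
            raise FloatingPointError(f"non-finite state at t={t:.4f}: {y}")
        k = min(int(t * rate), nn - 1)
        EL, ER, HL, HR = y
        XL = base + eL[k] - om * ER + eps * EL + sign * g * HL
        XR = base + eR[k] - om * EL + eps * ER + sign * g * HR
        if mode == _kernels.NOISE_IN_DRIVE:
            XL += nL[k]
            XR += nR[k]
        XL = max(XL, 0.0)
        XR = max(XR, 0.0)
        dEL = (-EL + M * XL / (1.0 + XL**p)) / tau
        dER = (-ER + M * XR / (1.0 + XR**p)) / tau
        if mode == _kernels.NOISE_LATE:
            dEL += nL[k] / tau
            dER += nR[k] / tau
        dHL = (-HL + EL) / tauh
        dHR = (-HR + ER) / tauh
        if mode == _kernels.NOISE_IN_ADAPTATION:
            dHL += nL[k] / tauh
            dHR += nR[k] / tauh
        return (dEL, dER, dHL, dHR)

    t_eval = np.arange(0.0, duration + readout_dt / 2, readout_dt)
    sol = solve_ivp(
        rhs,
        (0.0, duration),
        [params.init_perturb, 0.0, 0.0, 0.0],
        t_eval=t_eval,
        rtol=rtol,
        atol=1e-9,
        max_step=internal_left.dt,
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"solver failed: {sol.message}; last state {sol.y[:, -1]}")
    EL, ER, HL, HR = sol.y
    return TrialResult(
        t=sol.t,
        E_L=np.maximum(EL, 0.0),
        E_R=np.maximum(ER, 0.0),
        H_L=HL,
        H_R=HR,
        params=params,
        meta={
            "engine": "adaptive",
            "rtol": rtol,
            "external_left": external_left.meta,
            "external_right": external_right.meta,
            "internal_left": internal_left.meta,
            "internal_right": internal_right.meta,
        },
    )


def integrate_trial_fixed(
    params: ModelParams,
    external_left: NoiseStream,
    external_right: NoiseStream,
    internal_left: NoiseStream,
    internal_right: NoiseStream,
    duration: float = 60.0,
    dt: float = FIXED_DT,
    readout_dt: float = READOUT_DT,
) -> TrialResult:
    """Fixed-step RK4 integration (numba kernel) of one trial.

    The fast path used by the experiment layer; agrees with
    :func:`integrate_trial` to solver tolerance (validated in the tests).
    ``dt`` must divide the readout interval.
    """
    if params.variant is Variant.NO_OSCILLATOR:
        raise ValueError("NO_OSCILLATOR has no dynamics; use no_oscillator_percept")
    internal_left, internal_right = apply_variant(params, internal_left, internal_right)
    _check_streams(duration, external_left, external_right, internal_left, internal_right)
    stride = int(round(readout_dt / dt))
    if abs(stride * dt - readout_dt) > 1e-12:
        raise ValueError(f"dt={dt} must divide the readout interval {readout_dt}")
    n_steps = int(round(duration / dt))
    s = params.contrast_scale
    out = _kernels.rk4_rivalry(
        np.ascontiguousarray(external_left.samples / s),
        np.ascontiguousarray(external_right.samples / s),
        np.ascontiguousarray(internal_left.samples / s),
        np.ascontiguousarray(internal_right.samples / s),
        1.0 / internal_left.dt,
        dt,
        n_steps,
        stride,
        params.epsilon,
        params.omega,
        params.M,
        params.g,
        params.tau,
        params.tau_h,
        params.p,
        params.adaptation_sign,
        50.0 / s,
        50.0 / s,
        params.init_perturb,
        params.noise_mode,
    )
    t = np.arange(out.shape[0]) * readout_dt
    return TrialResult(
        t=t,
        E_L=out[:, 0],
        E_R=out[:, 1],
        H_L=out[:, 2],
        H_R=out[:, 3],
        params=params,
        meta={
            "engine": "fixed_rk4",
            "dt": dt,
            "external_left": external_left.meta,
            "external_right": external_right.meta,
            "internal_left": internal_left.meta,
            "internal_right": internal_right.meta,
        },
    )


def no_oscillator_percept(
    external_left: NoiseStream,
    external_right: NoiseStream,
    internal_left: NoiseStream,
    internal_right: NoiseStream,
    duration: float = 60.0,
    readout_dt: float = READOUT_DT,
) -> PerceptTimecourse:
    """Memoryless comparator percept: no inhibition, adaptation or dynamics.

    At each readout sample the percept is the sign of
    ``(L + N_L) - (R + N_R)``, i.e. dominance driven by external plus internal
    noise only.  With zero internal noise the percept is fully
    stimulus-determined and double-pass consistency is exactly 1.
    """
    _check_streams(duration, external_left, external_right, internal_left, internal_right)
    t = np.arange(0.0, duration + readout_dt / 2, readout_dt)
    d = (external_left.value_at(t) + internal_left.value_at(t)) - (
        external_right.value_at(t) + internal_right.value_at(t)
    )
    labels = np.where(d > 0, LEFT, np.where(d < 0, RIGHT, TIE)).astype(np.int8)
    return PerceptTimecourse(labels, readout_dt)
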