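"""Numba fixed-step RK4 kernel for the two-unit rivalry model.

This is the fast simulation path used by the experiment layer.  Noise and
external modulation are zero-order-held on their own sample grid; the
integration step is chosen to divide both the noise frame (1/120 s) and the
readout interval (1/100 s).  The kernel is validated in the test suite
against the adaptive reference solver.

``noise_mode`` selects where internal noise enters the wiring:
0 = inside the gain-control bracket (main model), 1 = in the adaptation
equation, 2 = added after the gain-control quotient (late noise).
"""

from __future__ import annotations

import numba
import numpy as np

NOISE_IN_DRIVE = 0
NOISE_IN_ADAPTATION = 1
NOISE_LATE = 2


@numba.njit(cache=True)
def rk4_rivalry(
    ext_left,
    ext_right,
    noise_left,
    noise_right,
    sample_rate,
    dt,
    n_steps,
    readout_stride,
    epsilon,
    omega,
    M,
    g,
    tau,
    tau_h,
    p,
    adaptation_sign,
    base_left,
    base_right,
    init_perturb,
    noise_mode,
):
    """Integrate one 60 s-style trial; returns (n_out, 4) readout of E_L, E_R, H_L, H_R.

    All contrast inputs are expected on the fraction scale (0.5 = 50%
    Michelson); readout E values are floored at zero.
    """
    EL = init_perturb
    ER = 0.0
    HL = 0.0
    HR = 0.0
    nn = noise_left.shape[0]
    n_out = n_steps // readout_stride + 1
    out = np.empty((n_out, 4))
    out[0, 0] = EL if EL > 0.0 else 0.0
    out[0, 1] = ER if ER > 0.0 else 0.0
    out[0, 2] = HL
    out[0, 3] = HR
    t = 0.0
    for i in range(n_steps):
        yEL = EL
        yER = ER
        yHL = HL
        yHR = HR
        aEL = 0.0
        aER = 0.0
        aHL = 0.0
        aHR = 0.0
        for stage in range(4):
            if stage == 0:
                ts = t
                w = 1.0
            elif stage < 3:
                ts = t + 0.5 * dt
                w = 2.0
            else:
                ts = t + dt
                w = 1.0
            k = int(ts * sample_rate)
            if k >= nn:
                k = nn - 1
            NL = noise_left[k]
            NR = noise_right[k]
            XL = base_left + ext_left[k] - omega * yER + epsilon * yEL + adaptation_sign * g * yHL
            XR = base_right + ext_right[k] - omega * yEL + epsilon * yER + adaptation_sign * g * yHR
            if noise_mode == NOISE_IN_DRIVE:
                XL += NL
                XR += NR
            if XL < 0.0:
                XL = 0.0
            if XR < 0.0:
                XR = 0.0
            dEL = (-yEL + M * XL / (1.0 + XL**p)) / tau
            dER = (-yER + M * XR / (1.0 + XR**p)) / tau
            if noise_mode == NOISE_LATE:
                dEL += NL / tau
                dER += NR / tau
            dHL = (-yHL + yEL) / tau_h
            dHR = (-yHR + yER) / tau_h
            if noise_mode == NOISE_IN_ADAPTATION:
                dHL += NL / tau_h
                dHR += NR / tau_h
            aEL += w * dEL
            aER += w * dER
            aHL += w * dHL
            aHR += w * dHR
            if stage < 2:
                h = 0.5 * dt
            else:
                h = dt
            yEL = EL + h * dEL
            yER = ER + h * dER
            yHL = HL + h * dHL
            yHR = HR + h * dHR
        EL += dt / 6.0 * aEL
        ER += dt / 6.0 * aER
        HL += dt / 6.0 * aHL
        HR += dt / 6.0 * aHR
        t += dt
        if (i + 1) % readout_stride == 0:
            j = (i + 1) // readout_stride
            out[j, 0] = EL if EL > 0.0 else 0.0
            out[j, 1] = ER if ER > 0.0 else 0.0
            out[j, 2] = HL
            out[j, 3] = HR
    return out
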