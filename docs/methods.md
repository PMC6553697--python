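# Methods

## Model

Two units representing the left- and right-eye stimuli compete through
mutual inhibition, each with slow self-adaptation, contrast gain control
and additive internal noise:

```
τ dE_i/dt  = −E_i + M·[X_i]₊ / (1 + [X_i]₊^p)
X_i        = C_i − ω·E_j + ε·E_i − g·H_i + N_i        (j the other unit)
τ_h dH_i/dt = −H_i + E_i
```

`C_i` is the stimulus contrast to eye *i* (50% Michelson mean plus the
experimental contrast modulation), `N_i` the internal noise, and `[·]₊`
half-wave rectification. The reported percept at each readout sample is
the unit with the larger response; exact ties are labelled TIE.

With no noise and equal contrast, the model settles into an anti-phase
relaxation oscillation: adaptation (`H`) erodes the dominant unit's drive
over seconds until the suppressed unit escapes from inhibition. Noise
perturbs the timing of these escapes, which is what couples the percept
to external contrast modulations and makes the double-pass consistency
informative about internal noise.

### Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| ε | self-excitation | 0.2 | – |
| ω | mutual inhibition | 3.5 | – |
| M | response gain | 1.0 | – |
| g | adaptation strength | 3.0 | – |
| τ | excitatory time constant | 0.015 | s |
| τ_h | adaptation time constant | 4.0 | s |
| p | gain-control exponent | 0.8 | – |
| α | internal-noise spectral exponent (amplitude ∝ f^−α) | 1.0 | – |
| SD | internal-noise standard deviation | 16 | % Michelson contrast |

All model constants are fixed; only the internal-noise specification
(α, SD), the stimulus condition and the variant wiring vary across
simulated experiments.

### Design choices on points the equations leave open

* **Contrast scale.** The drive operates on a fraction scale (50%
  Michelson → 0.5). The gain-control quotient has an implicit
  semi-saturation constant of 1, so a mid-contrast stimulus must sit near
  the knee of the nonlinearity: at `X ≈ 50` the quotient saturates (local
  gain ≈ 0.01) and no rivalry oscillation exists at all, while at
  `X ≈ 0.5` the printed parameters produce seconds-scale alternations.
  The public API keeps % Michelson units; the model divides by 100
  (`ModelParams.contrast_scale`) at its boundary. Internal noise is
  scaled identically, preserving the linear summation of noise and
  stimulus inside the bracket.
* **Adaptation sign.** Adaptation is suppressive (−g·H). Since `H` tracks
  `E`, a positive sign is runaway self-excitation: the model locks onto
  one percept permanently (verified numerically). The opposite wiring
  remains selectable via `ModelParams.adaptation_sign`.
* **Exponent placement.** The denominator is `1 + [X]₊^p`. A dialect with
  the bracket exponentiated as a whole behaves nearly identically at the
  operating point.

### Variants

* `MAIN` — noise inside the gain-control bracket (numerator and
  denominator).
* `ADAPTATION_NOISE` — bracket noise removed; `τ_h dH/dt = −H + E + N`.
* `SHARED_NOISE` — one stream injected into both units. Under symmetric
  inputs and symmetric initial conditions the two responses are then
  identical for all time (common noise cannot break symmetry); the test
  suite asserts this exactly.
* `LATE_NOISE` — bracket noise removed; `N/τ` added to dE/dt after the
  quotient.
* `NO_OSCILLATOR` — no dynamics at all: the percept at each sample is the
  sign of `(L + N_L) − (R + N_R)`. With zero internal noise this
  comparator is fully stimulus-determined (consistency exactly 1); with
  no external modulation it sits at chance (0.5).

## Noise synthesis

* **Internal (power-law) noise**: Fourier synthesis on a 120 Hz grid
  (matching a 120 Hz display timebase). Amplitude coefficients ∝ f^−α
  with DC and Nyquist zeroed; phases i.i.d. uniform on (−π, π). Each
  realization is demeaned and rescaled so its sample SD equals the nominal
  level exactly — the per-trial noise level is a controlled quantity, not
  a random one. The left/right pair shares the deterministic amplitude
  profile and differs only in phases, making the streams spectrally
  identical but statistically independent.
* **External (bandpass) noise**: Gaussian white noise masked in the
  frequency domain to the octave `[f_c/√2, f_c·√2]` (brick wall), then
  demeaned and rescaled. The filter shape is a declared dialect — the
  brick wall is the simplest reproducible reading of a one-octave band —
  and all out-of-band power is exactly zero, which the tests exploit.
  Antiphase conditions negate one stream sample-for-sample (r = −1);
  monocular conditions reuse the independent statistics with a different
  tag in the stream metadata.
* **Physical range**: displayed contrast is `50 + modulation`, clipped to
  [0, 100] with clip events counted; at SD ≤ 16% clipping is a > 3σ event.
* **Seeding**: a master seed expands through `numpy` SeedSequence spawn
  keys into per-repetition, per-pass, per-stream substreams, so any trial
  of a campaign is reproducible in isolation and double-pass repetitions
  reuse bit-identical external streams.

## Numerical integration

* Reference path: `scipy.integrate.solve_ivp` (RK45), rtol 1e-6, maximum
  step one noise frame (1/120 s) so no zero-order-hold segment is skipped.
  Noise is zero-order-held on its 120 Hz grid — matching frame-wise
  stimulus delivery and avoiding invented smoothness.
* Fast path: a numba fixed-step RK4 kernel at dt = 1/600 s (five steps per
  noise frame; 600 = lcm(120, 100) so the step divides both the noise
  frame and the readout interval). Noise-free trajectories agree with the
  adaptive path within 1e-4 RMS (asserted), the deterministic alternation
  period within 1%, and noisy-trial summary statistics are insensitive to
  halving dt. The experiment layer uses this path by default
  (`engine="fast"`); `engine="adaptive"` switches every trial to the
  reference solver.
* Initial conditions: all states zero plus a 1e-6 perturbation of E_L to
  break exact symmetry in noise-free runs. The first 2 s of every trial
  are discarded before all metrics (onset transient; configurable).
* Readout: 100 Hz uniform sampling, responses floored at zero.

## Metrics

* **Epochs**: maximal runs of a constant percept label. TIE runs are
  absorbed into the preceding epoch by default (mixed percepts are not
  analysed as events); a `separate` policy is available. Epochs touching
  either end of the analysed window are censored and excluded from
  duration statistics.
* **Durations**: arithmetic mean of complete epochs; histograms on 30
  log-spaced bins over [0.1, 30] s (durations outside the range are
  clipped into the outer bins so counts always total the epoch count).
* **Consistency**: fraction of jointly non-TIE samples with equal labels
  across the two passes of one repetition, then averaged across
  repetitions (per-pair-then-average). Chance is 0.5.
* **Correlations**: percepts coded LEFT = +1, RIGHT = −1, TIE = 0; Pearson
  coefficients per lag over the overlapping region. Negative lags mean the
  percept trails the stimulus. For a percept that is the sign of a
  Gaussian contrast difference, the zero-lag coefficient is
  E|X|/σ = √(2/π) ≈ 0.798, which anchors the cross-correlation tests; for
  bandpass stimuli the correlation stays positive at small positive lags
  because slow noise predicts its own near future.

## Synthetic observers

`generate_renewal_percepts` emulates the statistical signature of human
reports — alternating epochs with gamma-distributed durations (default
shape 4, scale 0.675 s, mean 2.7 s) and i.i.d. TIE insertions at 3.2% of
samples — so the metrics and pipeline are testable without the ODE model.
It deliberately omits serial epoch-to-epoch correlations, response lags,
stimulus coupling and observer biases; passing tests therefore validate
the *analysis* code, not the realism of the renewal process.
`generate_stimulus_locked_percepts` provides the complementary fixture:
a percept with known stimulus coupling and lag. Published group-level
summary values (baseline mean 2.7 s, baseline consistency 0.53, peak
consistency 0.72 at 1/8 Hz / 16%) ship as a JSON fixture with per-cell
provenance tags for the model–human comparison; they are fixture
constants, not quantities this package recomputes.

## Problem sizes

Simulated campaigns in the test suite run at reduced repetition counts
chosen so sampling error stays well below each asserted effect: 200
repetitions for the baseline condition (SEM ≈ 0.05 s on duration, ≈ 0.007
on consistency), 100 repetitions per cell for the sign and monotonicity
checks across the internal-noise sweep and the 26-condition grid, and 400
repetitions per cell for two checks that resolve small differences — the
consistency argmax across frequencies (the 1/8 vs 1/4 Hz gap is ≈ 0.016)
and the adaptation-noise flatness ratio (the range of a flat five-point
curve is inflated ≈ 2.3 SE by sampling noise). The full 1000-repetition
scale remains available through `ExperimentPlan`/`RunConfig`.

## Known limitations

* **Baseline dominance duration.** With every dialect explored
  (integration step, solver tolerance, noise grid rate, input scaling,
  transient and censoring policies), the unmodulated baseline with pink
  16% internal noise yields a mean dominance duration of ≈ 4.6–4.7 s,
  whereas the reference value for this configuration is 3.18 s; the
  relative sensitivity of duration to α is also stronger here than in the
  reference account. The original implementation's noise delivery into
  the adaptive solver is not fully specified, and no faithful reading of
  the printed equations reproduced the shorter value. Quantities that
  depend on this scale inherit the bias: in the model–human ranking, the
  (α = 0.5, SD = 8%) cell edges out (α = 1, SD = 16%) because the α = 1
  durations run ≈ 1.2 s long. Consistency-based results are unaffected:
  the baseline consistency (≈ 0.50), the tuning of consistency to 1/8 Hz,
  its growth with modulation contrast, its decline with internal noise,
  and all variant orderings reproduce the reference behaviour.
* The percept readout has no response lag, smoothing or hysteresis, so
  model cross-correlation peaks sit closer to zero lag than human ones.
* Mixed percepts arise only as exact response ties (plus the synthetic
  TIE insertions); the model does not represent piecemeal rivalry.
* The no-oscillator comparator is memoryless by construction; it is a
  bound on stimulus-driven behaviour, not a model of monocular rivalry.
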