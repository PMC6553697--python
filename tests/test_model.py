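"""Model dynamics: fixed points, oscillation, solver agreement, variants."""

import numpy as np
import pytest
from scipy.optimize import bisect

import rivalnoise as rn
from rivalnoise.model import FIXED_DT, ModelState, no_oscillator_percept


def stream_of(values, dt=1.0 / 120.0):
    return rn.NoiseStream(np.asarray(values, dtype=float), dt)


def constant_stream(value, duration=60.0, dt=1.0 / 120.0):
    return stream_of(np.full(int(round(duration / dt)), value), dt)


class TestDrive:
    def test_origin_is_fixed_point(self):
        d = rn.drive(ModelState(0, 0, 0, 0), {"L": 0.0, "R": 0.0}, rn.ModelParams())
        np.testing.assert_array_equal(d, 0.0)

    def test_rectification_under_strong_inhibition(self):
        """With the drive rectified to zero, E decays with pure leak -E/tau."""
        params = rn.ModelParams()
        state = ModelState(E_L=0.5, E_R=5.0, H_L=0.0, H_R=0.0)  # omega*E_R >> L
        d = rn.drive(state, {"L": 0.0, "R": 0.0}, params)
        assert d[0] == pytest.approx(-0.5 / params.tau)

    def test_nonfinite_state_raises(self):
        with pytest.raises(FloatingPointError):
            rn.drive(ModelState(np.nan, 0, 0, 0), {"L": 0.0, "R": 0.0}, rn.ModelParams())

    def test_noise_placement_by_variant(self):
        """Internal noise moves between the drive bracket, H equation and post-quotient term."""
        state = ModelState(0.2, 0.05, 0.0, 0.0)  # drive bracket stays positive
        inputs = {"L": 50.0, "R": 50.0, "N_L": 10.0, "N_R": -10.0}
        base = {"L": 50.0, "R": 50.0}
        main = rn.drive(state, inputs, rn.ModelParams(variant=rn.Variant.MAIN))
        main0 = rn.drive(state, base, rn.ModelParams(variant=rn.Variant.MAIN))
        assert main[0] != main0[0] and main[2] == main0[2]
        adapt = rn.drive(state, inputs, rn.ModelParams(variant=rn.Variant.ADAPTATION_NOISE))
        adapt0 = rn.drive(state, base, rn.ModelParams(variant=rn.Variant.ADAPTATION_NOISE))
        assert adapt[0] == adapt0[0]  # E equation untouched
        params = rn.ModelParams(variant=rn.Variant.ADAPTATION_NOISE)
        assert adapt[2] - adapt0[2] == pytest.approx(0.1 / params.tau_h)
        late = rn.drive(state, inputs, rn.ModelParams(variant=rn.Variant.LATE_NOISE))
        late0 = rn.drive(state, base, rn.ModelParams(variant=rn.Variant.LATE_NOISE))
        assert late[0] - late0[0] == pytest.approx(0.1 / params.tau)  # additive, outside quotient


class TestFixedPoint:
    def test_matches_bisection_oracle(self, zero_stream):
        """With omega=g=0 the steady state solves E = M[x+eps E]/(1+[x+eps E]^p).

        The root is located independently by bisection on the model's internal
        contrast scale; the integrated trajectory must converge to it.
        """
        params = rn.ModelParams(omega=0.0, g=0.0, internal_sd=0.0)
        x = 50.0 / params.contrast_scale

        def residual(E):
            X = max(x + params.epsilon * E, 0.0)
            return params.M * X / (1.0 + X**params.p) - E

        e_star = bisect(residual, 0.0, 10.0, xtol=1e-12)
        ext = constant_stream(0.0)
        trial = rn.integrate_trial(params, ext, ext, ext, ext, duration=2.0, rtol=1e-9)
        # 2 s >> 50*tau: transient fully decayed
        assert trial.E_L[-1] == pytest.approx(e_star, abs=1e-6)
        assert trial.E_R[-1] == pytest.approx(e_star, abs=1e-6)

    def test_leak_decay_without_input(self, zero_stream):
        """Total stimulus contrast zero (external stream cancels the 50% mean)."""
        params = rn.ModelParams(init_perturb=0.1, internal_sd=0.0)
        dark = constant_stream(-50.0, duration=1.0)
        z = zero_stream(duration=1.0)
        trial = rn.integrate_trial(params, dark, dark, z, z, duration=1.0)
        assert trial.E_L[-1] < 1e-8
        after = trial.E_L[trial.t > 0.05]
        assert np.all(np.diff(after) <= 1e-12)  # monotone decay after transient


@pytest.fixture(scope="module")
def noise_free_trials():
    params = rn.ModelParams(internal_sd=0.0)
    z = rn.NoiseStream(np.zeros(int(60.0 * 120)), 1.0 / 120.0)
    fixed = rn.integrate_trial_fixed(
        params, z, z, z, z, duration=60.0, dt=params.tau / 20.0, readout_dt=params.tau / 20.0 * 5
    )
    adaptive = rn.integrate_trial(
        params, z, z, z, z, duration=60.0, rtol=1e-8, readout_dt=params.tau / 20.0 * 5
    )
    return fixed, adaptive


class TestOscillation:
    @staticmethod
    def switch_times(trial):
        s = np.sign(trial.E_L - trial.E_R)
        idx = np.flatnonzero(np.diff(s) != 0)
        return trial.t[idx]

    def test_sustained_alternation_with_stable_period(self, noise_free_trials):
        """Equal 50% contrast with a tiny initial asymmetry yields anti-phase relaxation
        oscillations whose period is stable after the onset transient."""
        fixed, _ = noise_free_trials
        switches = self.switch_times(fixed)
        assert len(switches) >= 4
        epochs = np.diff(switches)[1:]  # drop the onset epoch
        assert epochs.std() / epochs.mean() < 0.02
        # winner margin alternates sign: true mutual exclusivity of the percept
        s = np.sign(fixed.E_L - fixed.E_R)
        assert set(np.unique(s[fixed.t > 2.0])) == {-1.0, 1.0}

    def test_adaptive_matches_fixed_step_period(self, noise_free_trials):
        fixed, adaptive = noise_free_trials
        p_fixed = np.diff(self.switch_times(fixed))[1:].mean()
        p_adaptive = np.diff(self.switch_times(adaptive))[1:].mean()
        assert p_adaptive == pytest.approx(p_fixed, rel=0.01)

    def test_adaptive_vs_fixed_step_trajectories(self, noise_free_trials):
        """Trajectory agreement within 1e-4 RMS on noise-free trials (dt = tau/20)."""
        fixed, adaptive = noise_free_trials
        n = min(fixed.E_L.size, adaptive.E_L.size)
        rms = np.sqrt(np.mean((fixed.E_L[:n] - adaptive.E_L[:n]) ** 2))
        assert rms < 1e-4

    def test_rectified_readout_nonnegative(self):
        il, ir = rn.make_powerlaw_pair(rn.PowerlawSpec(1.0, 16.0, 10.0), 21, 22)
        z = rn.NoiseStream(np.zeros(il.n), il.dt)
        trial = rn.integrate_trial_fixed(rn.ModelParams(), z, z, il, ir, duration=10.0)
        assert trial.E_L.min() >= 0.0 and trial.E_R.min() >= 0.0

    def test_integrated_noise_is_not_white(self):
        """With white internal noise and only the leak active, successive E samples
        stay strongly correlated: integration colours the output."""
        params = rn.ModelParams(omega=0.0, g=0.0, internal_alpha=0.0)
        il, ir = rn.make_powerlaw_pair(rn.PowerlawSpec(0.0, 16.0, 30.0), 5, 6)
        z = rn.NoiseStream(np.zeros(il.n), il.dt)
        trial = rn.integrate_trial_fixed(params, z, z, il, ir, duration=30.0)
        e = trial.E_L[trial.t > 1.0]
        lag1 = np.corrcoef(e[:-1], e[1:])[0, 1]
        assert lag1 > 0.5


class TestPercept:
    def test_constant_winner(self):
        t = np.arange(0, 1, 0.01)
        trial = rn.TrialResult(t, np.ones_like(t), np.zeros_like(t), t * 0, t * 0, rn.ModelParams())
        assert (trial.percept().labels == 1).all()

    def test_all_tie(self):
        t = np.arange(0, 1, 0.01)
        trial = rn.TrialResult(t, np.ones_like(t), np.ones_like(t), t * 0, t * 0, rn.ModelParams())
        assert (trial.percept().labels == 0).all()

    def test_single_crossing(self):
        t = np.arange(0, 1, 0.01)
        e_l = 1.005 - t  # crosses e_r = t at t* = 0.5025, between samples
        trial = rn.TrialResult(t, e_l, t.copy(), t * 0, t * 0, rn.ModelParams())
        labels = trial.percept().labels
        changes = np.flatnonzero(np.diff(labels))
        assert len(changes) == 1
        assert t[changes[0]] == pytest.approx(0.5025, abs=0.011)


class TestVariants:
    def test_shared_noise_preserves_symmetry(self):
        """A common noise stream cannot break left/right symmetry."""
        params = rn.ModelParams(variant=rn.Variant.SHARED_NOISE, init_perturb=0.0)
        il, ir = rn.make_powerlaw_pair(rn.PowerlawSpec(1.0, 16.0, 20.0), 31, 32)
        z = rn.NoiseStream(np.zeros(il.n), il.dt)
        trial = rn.integrate_trial_fixed(params, z, z, il, ir, duration=20.0)
        np.testing.assert_array_equal(trial.E_L, trial.E_R)

    def test_apply_variant_shared_uses_one_stream(self):
        il, ir = rn.make_powerlaw_pair(rn.PowerlawSpec(1.0, 16.0, 2.0), 1, 2)
        left, right = rn.apply_variant(rn.ModelParams(variant=rn.Variant.SHARED_NOISE), il, ir)
        assert right is left
        left, right = rn.apply_variant(rn.ModelParams(), il, ir)
        assert right is ir

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            rn.ModelParams(variant="NOT_A_VARIANT")

    def test_no_oscillator_is_stimulus_determined_without_internal_noise(self):
        ext_l = rn.make_bandpass_noise(rn.BandpassSpec(0.125, 16.0, 60.0, seed=1))
        ext_r = rn.make_bandpass_noise(rn.BandpassSpec(0.125, 16.0, 60.0, seed=2))
        zero = rn.NoiseStream(np.zeros(ext_l.n), ext_l.dt)
        p1 = no_oscillator_percept(ext_l, ext_r, zero, zero)
        p2 = no_oscillator_percept(ext_l, ext_r, zero, zero)
        assert rn.consistency(p1, p2) == 1.0
        d = ext_l.value_at(p1.times) - ext_r.value_at(p1.times)
        expected = np.sign(d)
        assert (p1.labels == expected).mean() > 0.999

    def test_no_oscillator_rejected_by_integrators(self):
        params = rn.ModelParams(variant=rn.Variant.NO_OSCILLATOR)
        z = rn.NoiseStream(np.zeros(120), 1.0 / 120.0)
        with pytest.raises(ValueError):
            rn.integrate_trial(params, z, z, z, z, duration=1.0)
        with pytest.raises(ValueError):
            rn.integrate_trial_fixed(params, z, z, z, z, duration=1.0)


def test_short_stream_rejected():
    z = rn.NoiseStream(np.zeros(120), 1.0 / 120.0)  # one second only
    with pytest.raises(ValueError):
        rn.integrate_trial_fixed(rn.ModelParams(), z, z, z, z, duration=10.0)


def test_trial_serialisation_roundtrip(tmp_path):
    il, ir = rn.make_powerlaw_pair(rn.PowerlawSpec(1.0, 16.0, 5.0), 41, 42)
    z = rn.NoiseStream(np.zeros(il.n), il.dt)
    trial = rn.integrate_trial_fixed(rn.ModelParams(), z, z, il, ir, duration=5.0)
    path = str(tmp_path / "trial.tsv")
    trial.to_files(path)
    data = np.loadtxt(path, delimiter="\t")
    np.testing.assert_allclose(data[:, 1], trial.E_L, rtol=1e-6)
    np.testing.assert_array_equal(data[:, 5].astype(int), trial.percept().labels)
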