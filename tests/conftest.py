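import numpy as np
import pytest

import rivalnoise as rn


@pytest.fixture(scope="session", autouse=True)
def _warm_kernel():
    """Compile the numba kernel once so per-test timings are meaningful."""
    il, ir = rn.make_powerlaw_pair(rn.PowerlawSpec(1.0, 16.0, 1.0), 1, 2)
    zero = rn.NoiseStream(np.zeros(il.n), il.dt)
    rn.integrate_trial_fixed(rn.ModelParams(), zero, zero, il, ir, duration=1.0)


@pytest.fixture
def pink_spec():
    return rn.PowerlawSpec(alpha=1.0, sd=16.0, duration=60.0, seed=11)


@pytest.fixture
def bp_spec():
    return rn.BandpassSpec(centre_freq=0.125, sd=16.0, duration=60.0, seed=7)


def make_percept(labels, dt=0.01):
    return rn.PerceptTimecourse(np.asarray(labels, dtype=np.int8), dt)


@pytest.fixture
def zero_stream():
    def factory(duration=60.0, dt=1.0 / 120.0):
        return rn.NoiseStream(np.zeros(int(round(duration / dt))), dt)

    return factory
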