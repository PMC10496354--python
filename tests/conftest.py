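import numpy as np
import pytest
from hypothesis import settings

import respigate as rg

settings.register_profile("suite", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def liver_trace():
    """A 120 s liver-preset trace (noisy, variable cycles)."""
    params = rg.params_from_preset("liver", duration=120.0, seed=3)
    return rg.simulate_trace(params)


@pytest.fixture(scope="session")
def regular_trace():
    """A noiseless, perfectly periodic trace (period 4 s, 5 Hz)."""
    params = rg.BreathingParams(
        mean_period=4.0, period_sd=0.0, mean_amp_si=12.0, mean_amp_ap=4.0,
        mean_amp_lr=3.0, amp_sd_frac=0.0, drift_mm_per_min=0.0, noise_sd=0.0,
        duration=120.0, seed=1)
    return rg.simulate_trace(params)


def linear_recursion_trace(duration=120.0, dt=0.2):
    """A trace that satisfies a short linear recursion exactly.

    A constant plus three sinusoids is annihilated by a 7-tap linear
    recursion, so a 15-tap least-squares predictor can forecast it to
    machine precision.
    """
    t = np.arange(int(duration / dt) + 1) * dt
    y = (10.0 + 4.0 * np.sin(2 * np.pi * t / 4.0)
         + 1.5 * np.sin(2 * np.pi * t / 2.0 + 0.3)
         + 0.8 * np.sin(2 * np.pi * t / 7.1 + 1.1))
    z = np.zeros_like(y)
    return rg.Trace(t, y, z, z, np.abs(y - y.mean()), label="recursion")


@pytest.fixture(scope="session")
def ar_trace():
    return linear_recursion_trace()
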