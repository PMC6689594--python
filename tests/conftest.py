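import numpy as np
import pytest

from hyotrack.simulate import SwallowSimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_config():
    """Noise-free generator settings: every stochastic term switched off."""
    return SwallowSimConfig(sensor_noise_sd=0.0, vibration_snr=0.0,
                            rater_jitter_sd=0.0, n_raters=2, seed=7)


@pytest.fixture(scope="session")
def small_clean_cohort():
    """12 participants x 2 noise-free swallows, shared across tests."""
    cfg = SwallowSimConfig(sensor_noise_sd=0.0, vibration_snr=0.0,
                           rater_jitter_sd=0.0, n_raters=2, seed=21)
    return simulate_cohort(12, 2, cfg)
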