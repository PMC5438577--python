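import numpy as np
import pytest

from crpkit import GaitModel, HopModel, RunConfig


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def clean_gait_model():
    """Noiseless, jitter-free walking with known 30/60 deg couple lags."""
    return GaitModel(jitter_sd=0.0, noise_sd=0.0, couple_lag_ts=30.0, couple_lag_sf=60.0)


@pytest.fixture
def clean_hop_model():
    return HopModel(jitter_sd=0.0, noise_sd=0.0, couple_lag_ts=30.0, couple_lag_sf=60.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
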