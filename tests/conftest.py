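import numpy as np
import pytest

from memstdp import DevicePlasticityParams, MemristorState


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quiet_params():
    """Calibrated default device with all stochasticity switched off."""
    return DevicePlasticityParams.calibrated(sigma_cycle=0.0, sigma_read=0.0)


@pytest.fixture
def quiet_device(quiet_params):
    return MemristorState(quiet_params.g_mid, quiet_params)
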