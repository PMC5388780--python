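import numpy as np
import pytest

from antnav import KinematicsParams, PIParams, calibrate_metric_scale, preferred_directions


@pytest.fixture(scope="session")
def dirs18():
    return preferred_directions(18)


@pytest.fixture(scope="session")
def pi18():
    return PIParams(n_neurons=18)


@pytest.fixture(scope="session")
def kin():
    return KinematicsParams()


@pytest.fixture(scope="session")
def calib18(pi18, kin):
    """Zero-noise metric calibration for the default circuit."""
    return calibrate_metric_scale(pi18, kin.step_len)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
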