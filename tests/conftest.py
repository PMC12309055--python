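import numpy as np
import pytest

from batvoc import SignalRecord, TVARModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_noise_signal(rng):
    return SignalRecord(rng.normal(size=500), sample_rate_hz=1.0, id="wn")


@pytest.fixture
def ar1_model():
    """Stationary AR(1) with coefficient 0.9, unit noise."""
    return TVARModel(order_p=1, coeff_trajectory=np.full((2001, 1), 0.9))


def stationary_ar_model(coeffs, n_points, noise_variance=1.0):
    coeffs = np.atleast_1d(np.asarray(coeffs, float))
    traj = np.tile(coeffs, (n_points, 1))
    return TVARModel(order_p=coeffs.size, coeff_trajectory=traj,
                     noise_variance=noise_variance)
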