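import numpy as np
import pytest

from pbostim.pgp import GPHyperparameters, PersonalizedGP


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_gp(rng):
    """A fitted 6-point personalized GP with fixed hyperparameters."""
    Z = rng.random((6, 3))
    y = rng.standard_normal(6)
    model = PersonalizedGP()
    model.fit(Z, y, hyper=GPHyperparameters(sigma_l=0.3, sigma_p=0.4, sigma_n2=0.1))
    return model
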