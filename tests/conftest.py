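import numpy as np
import pytest

from abtp import herd, thi
from abtp.models import ABTPParams


@pytest.fixture(scope="session")
def default_herd():
    """320-animal synthetic herd with the default (study-like) moments."""
    return herd.generate_herd(herd.HerdConfig(seed=1))


@pytest.fixture(scope="session")
def labeled_default(default_herd):
    return thi.label_abnormal(default_herd)


@pytest.fixture(scope="session")
def logistic_truth():
    """Logistic ground truth with TT50 = 75 and slope 0.30 per THI unit."""
    return ABTPParams.from_logistic_coefficients(beta0=-22.5, beta1=0.30)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
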