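import warnings

import numpy as np
import pytest

from ionpairing.synthetic import ZERO_NOISE, get_preset


@pytest.fixture(scope="session")
def nacl_preset():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return get_preset("nacl")


@pytest.fixture(scope="session")
def nahso4_preset():
    return get_preset("nahso4")


@pytest.fixture(scope="session")
def nah2po4_preset():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return get_preset("nah2po4")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def zero_noise():
    return ZERO_NOISE
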