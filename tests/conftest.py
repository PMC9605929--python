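import numpy as np
import pytest
from hypothesis import settings

from gliodx import AifParams, TissueParams, make_aif

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")

DEFAULT_PARAMS = TissueParams(F=60.0, BV=4.0, Ki=6.0, Ve=20.0)


@pytest.fixture(scope="session")
def aif300():
    """Population AIF on a 1 s grid over 5 minutes."""
    return make_aif(AifParams(), np.arange(300.0))


@pytest.fixture(scope="session")
def tumour_params():
    return DEFAULT_PARAMS


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
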