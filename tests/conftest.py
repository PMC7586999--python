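import numpy as np
import pytest

from divorseq.motifs import pfm_to_pwm
from divorseq.simulate import default_pfm


@pytest.fixture(scope="session")
def pfm():
    return default_pfm()


@pytest.fixture(scope="session")
def pwm(pfm):
    return pfm_to_pwm(pfm)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
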