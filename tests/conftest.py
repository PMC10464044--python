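import numpy as np
import pytest

from poolhet import ArmData


@pytest.fixture
def sat_100_50():
    return ArmData.from_counts("SAT", 100, 50)


@pytest.fixture
def rng():
    return np.random.default_rng(20230824)


def make_arm(label, n, responders, covariates=None):
    outcomes = np.zeros(n, dtype=np.int8)
    outcomes[:responders] = 1
    return ArmData(label=label, n=n, responders=responders,
                   outcomes=outcomes, covariates=covariates)
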