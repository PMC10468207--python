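import numpy as np
import pytest

from ihp import synth
from ihp.xlms import DEFAULT_DOMAIN_MAP


@pytest.fixture(scope="session")
def noiseless_timecourse():
    return synth.gen_timecourse(
        synth.KineticTruth(a1=0.6, r1=0.3, k2=0.004, noise_sd=0.0, seed=0)
    )


@pytest.fixture(scope="session")
def ihp_xl_table():
    return synth.gen_xl_table(
        synth.XlScenario(name="ihp", n_crosslinks=200, hetero_ratio=0.25, seed=42)
    )


@pytest.fixture(scope="session")
def exchange_xl_table():
    return synth.gen_xl_table(
        synth.XlScenario(name="exchange", n_crosslinks=400, hetero_ratio=0.25, seed=42)
    )


@pytest.fixture
def domain_map():
    return DEFAULT_DOMAIN_MAP


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
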