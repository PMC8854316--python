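import numpy as np
import pytest

from dotbias.observer import ObserverModel, SessionPlan, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def unbiased_block():
    """180-trial isolated block for a bias-free observer (reused by several
    fitting tests)."""
    obs = ObserverModel(aq=15, bias_low=0.0, bias_high=0.0)
    plan = SessionPlan(reference_numerosities=(15,), conditions=("isolated",))
    return simulate_session(obs, plan, np.random.default_rng(11))


@pytest.fixture(scope="session")
def biased_block():
    """180-trial connected block for an observer with a 27% low-regime bias."""
    obs = ObserverModel(aq=5, bias_low=0.27, bias_high=0.11)
    plan = SessionPlan(reference_numerosities=(15,), conditions=("connected",))
    return simulate_session(obs, plan, np.random.default_rng(12))
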