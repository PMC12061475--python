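import numpy as np
import pytest

from striatalrl.analysis import neural_session_from_sim, zscore_neurons
from striatalrl.spontaneous import SpontaneousConfig, run_spontaneous_session
from striatalrl.synth import generate_neural_session

# no-action offset calibrated once for the default spontaneous configuration
# (50 actions, beta=100); recomputed by the calibration test and the
# acceptance suite
LOG_C_NOGO = 205.078125


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def spontaneous_session():
    """A 5e4-step efference-model spontaneous session (shared; read-only)."""
    cfg = SpontaneousConfig(n_steps=50_000, log_c_nogo=LOG_C_NOGO)
    return run_spontaneous_session(cfg, np.random.default_rng(11))


@pytest.fixture(scope="session")
def spontaneous_neural(spontaneous_session):
    return zscore_neurons(neural_session_from_sim(spontaneous_session))


@pytest.fixture(scope="session")
def planted_session():
    """Synthetic session with planted efference-like structure + truth."""
    session, truth = generate_neural_session(seed=3)
    return zscore_neurons(session), truth
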