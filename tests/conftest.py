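import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metaconf import DesignSpec, ObserverParams, idealized_observer, \
    simulate_session

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design_spec():
    return DesignSpec()


@pytest.fixture(scope="session")
def ideal_session():
    """One session of an idealized observer with older-adult sensory noise."""
    return simulate_session(idealized_observer(6.0), seed=7,
                            participant_id="ideal")


@pytest.fixture(scope="session")
def noisy_session():
    """One session of an observer with moderate confidence noise."""
    params = ObserverParams(sigma_s=5.0, sigma_c=0.8, lapse=0.02)
    return simulate_session(params, seed=11, participant_id="noisy")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
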