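import numpy as np
import pytest

import asalab as al


@pytest.fixture(scope="session")
def default_male():
    return al.SubjectProfile("S001", "male", 30.0, 180.0, 80.0)


@pytest.fixture(scope="session")
def default_pk(default_male):
    return al.PKParameters.for_subject(default_male)


@pytest.fixture(scope="session")
def noiseless_session_config():
    """Deterministic session setup: exact breathalyzer, true-parameter controller."""
    return al.SessionConfig(reading_noise_sd=0.0)


@pytest.fixture(scope="session")
def always_work_log(default_male, default_pk, noiseless_session_config):
    """One full session of the relentless scripted worker (shared: it backs
    several clamp-fidelity and event-accounting checks)."""
    return al.run_session(
        default_male,
        default_pk,
        al.scripted_agent("always_alcohol"),
        noiseless_session_config,
        seed=3,
    )


@pytest.fixture(scope="session")
def reference_trial():
    """One simulated randomized trial at 200 subjects per arm with the
    default drug effect; shared across the population-level property tests."""
    return al.simulate_trial(al.CohortConfig(n_subjects=400), seed=11)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
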