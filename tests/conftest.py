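import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from contactkit import ContactProbMap, gen_chain

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20210413)


@pytest.fixture(scope="session")
def small_target():
    """A 40-residue compact chain with derived labels, reused across tests."""
    return gen_chain(40, seed=7, target_id="SYN_SMALL")


def random_prob_map(rng, L, target_id="T0001", sequence=None):
    """Random symmetric contact-probability map with zero diagonal."""
    upper = np.triu(rng.random((L, L)), k=1)
    return ContactProbMap(target_id=target_id, p=upper + upper.T, sequence=sequence)
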