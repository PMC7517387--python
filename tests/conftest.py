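import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic 64×64 phantom used across tests."""
    from vesselseg import PhantomSpec, generate_phantom

    return generate_phantom(PhantomSpec(size=64, seed=7))


@pytest.fixture(scope="session")
def phantom_pairs_small():
    """Six deterministic 64×64 phantoms."""
    from dataclasses import replace

    from vesselseg import PhantomSpec, generate_phantom

    base = PhantomSpec(size=64)
    return [generate_phantom(replace(base, seed=100 + s)) for s in range(6)]
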