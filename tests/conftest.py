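import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scene():
    """Default 512x512 phantom scene, shared across the suite."""
    from dsareg.phantom import gen_phantom

    return gen_phantom(seed=7)


@pytest.fixture(scope="session")
def small_scene():
    """256x256 phantom for fast pipeline-level tests."""
    from dsareg.phantom import PhantomParams, gen_phantom

    return gen_phantom(PhantomParams(size=(256, 256)), seed=5)


@pytest.fixture(scope="session")
def sim_pair(scene):
    from dsareg.phantom import simulate_pair

    return simulate_pair(scene.live, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
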