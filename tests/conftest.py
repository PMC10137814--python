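import pytest
from hypothesis import HealthCheck, settings

from cinevol.phantom import (
    PhantomParams,
    default_geometry,
    generate_phantom,
    small_geometry,
    small_params,
)

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_phantom():
    """A reduced noiseless phantom: fast enough for per-module tests."""
    return generate_phantom(small_params(), small_geometry(), seed=7)


@pytest.fixture(scope="session")
def default_phantom():
    """Full-size noiseless phantom at the clinical acquisition geometry."""
    return generate_phantom(PhantomParams(noise_sd=0.0), default_geometry(), seed=11)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Full-size phantom with the default 5%-of-blood-signal noise."""
    return generate_phantom(PhantomParams(), default_geometry(), seed=13)
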