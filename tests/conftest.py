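import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scarpipe.phantom import PhantomParams, generate_case

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> PhantomParams:
    return PhantomParams(n_patients=4, seed=11)


@pytest.fixture(scope="session")
def phantom_case(default_params):
    """One fully generated case (meshes + volumes + ground truth)."""
    return generate_case(default_params, 0)


@pytest.fixture(scope="session")
def mesh_only_case(default_params):
    """Case without volumes, for registration-only tests."""
    return generate_case(default_params, 1, include_volumes=False)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
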