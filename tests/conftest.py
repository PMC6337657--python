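import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """A 9-seed, 121-band scene spec small enough for per-test use."""
    from frostspec.synth import SceneSpec

    return SceneSpec(n_per_class=(3, 3, 3), n_bands=121, seed=7)


@pytest.fixture(scope="session")
def small_scene(small_spec):
    from frostspec.synth import make_scene

    return make_scene(small_spec)


@pytest.fixture(scope="session")
def corrected_scene(small_scene):
    from frostspec.hypercube import reflectance_correct

    cube, refs, truth = small_scene
    return reflectance_correct(cube, refs), truth
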