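import pytest
from hypothesis import HealthCheck, settings

from calcytox import AssayParams, DetectionParams, ImageSpec, WellSpec, \
    simulate_well

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def params() -> AssayParams:
    return AssayParams()


@pytest.fixture
def image_spec() -> ImageSpec:
    return ImageSpec()


@pytest.fixture
def small_image_spec() -> ImageSpec:
    """Fast 256-px field for unit tests; higher sampling keeps counts up."""
    return ImageSpec(width_px=256, height_px=256, sampled_fraction=0.2)


@pytest.fixture
def detection() -> DetectionParams:
    return DetectionParams()


def make_well(role="spontaneous", et=0.0, n=2000, seed=0,
              params=None):
    params = params or AssayParams()
    spec = WellSpec(role, et, n, seed=seed, well_id=f"{role}_{seed}")
    return simulate_well(spec, params)


@pytest.fixture
def well_factory():
    return make_well
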