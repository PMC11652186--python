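import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cfocr import PipelineConfig, SimParams

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def quick_params():
    """Low-depth generator settings for tests that only need structure,
    not full sequencing depth."""
    return SimParams(depth_ccr=10.0, depth_cv=0.0, seed=0)


@pytest.fixture(scope="session")
def fast_config():
    """Desk-scale pipeline configuration used by end-to-end tests."""
    return PipelineConfig(
        n_ocr=80, n_ccr=320, n_pocr=80, n_test_per_class=40,
        n_mc=200, B=300, calib_n=200, seed=0,
    )
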