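import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_scene_params():
    """Reduced-size study conditions for fast end-to-end tests."""
    from satquant import SceneParams

    return SceneParams(width=320, height=240, n_nuclei=25, pax7_fraction=0.2,
                       brdu_fraction=0.12, n_copositive=2)
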