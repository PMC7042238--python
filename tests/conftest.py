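import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rgcmosaic as rm

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_scene():
    """Mid-density vessel-free scene reused by detection tests."""
    spec = rm.SceneSpec(
        field_width_um=500.0, field_height_um=500.0,
        target_density_cells_per_mm2=1500.0, seed=11,
    )
    return rm.make_scene(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
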