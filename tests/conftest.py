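import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dtialps.synthetic import CohortConfig, GeometryConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20250922)


@pytest.fixture
def small_geom():
    """Compact imaging geometry used across ROI/ALPS tests."""
    return GeometryConfig()


@pytest.fixture
def tiny_cohort_config():
    """A 5/5/5 cohort with no exclusions and no index noise."""
    return CohortConfig(
        n_per_group={"PD": 5, "iRBD": 5, "HC": 5},
        exclusion_rates={},
        noise_sd_index=0.0,
        hemi_noise_sd=0.0,
        seed=7,
    )
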