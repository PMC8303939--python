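import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pelvitherm import ScanGeometry, simulate_session

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_geometry() -> ScanGeometry:
    return ScanGeometry(matrix=64, n_slices=9)


@pytest.fixture(scope="session")
def test_geometry() -> ScanGeometry:
    """Desk-scale grid used for recovery experiments."""
    return ScanGeometry(matrix=128, n_slices=15)


@pytest.fixture(scope="session")
def clean_session(test_geometry):
    """Noise-, drift- and artifact-free session: the PRFS round-trip case."""
    return simulate_session(
        geometry=test_geometry,
        air_motion_fraction=0.0,
        air_volume_ml=150.0,
        drift_rad=0.0,
        noise_sd_rad=0.0,
        air_artifact_rad=0.0,
        probe_noise_sd_c=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noisy_session(small_geometry):
    """Session with all confounders on, for end-to-end sanity checks."""
    return simulate_session(
        geometry=small_geometry,
        air_motion_fraction=0.3,
        air_volume_ml=180.0,
        drift_rad=0.05,
        noise_sd_rad=0.003,
        air_artifact_rad=0.3,
        probe_noise_sd_c=0.1,
        seed=7,
    )
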