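import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fazseg import PipelineConfig, generate_cohort, generate_sample
from fazseg.synthetic import SceneParams

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# The canonical study cohorts: n = 20 scenes at 256 x 256, base seed 101;
# the artifact cohort shares its geometry with the clean one and differs
# only in the artifact assignment (half motion stripes, half decentered).
COHORT_N = 20
COHORT_SEED = 101
COHORT_SHAPE = (256, 256)


@pytest.fixture(scope="session")
def clean_cohort():
    return generate_cohort(COHORT_N, base_seed=COHORT_SEED, artifact_fraction=0.0)


@pytest.fixture(scope="session")
def artifact_cohort():
    return generate_cohort(COHORT_N, base_seed=COHORT_SEED, artifact_fraction=1.0)


@pytest.fixture(scope="session")
def clean_sample():
    """One clean scene with moderate noise (seed 7, default parameters)."""
    return generate_sample(SceneParams(seed=7))


@pytest.fixture(scope="session")
def noiseless_sample():
    """Two-level scene: no noise, no vessels."""
    return generate_sample(SceneParams(seed=7, noise_sd=0.0, vessel_density=0.0))


@pytest.fixture()
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
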