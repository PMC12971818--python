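import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ttgsim import SyntheticKneeParams, sample_cohort, simulate_cohort, zero_noise

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params() -> SyntheticKneeParams:
    """The study conditions: the generator's default cohort (n = 56, seed 0)."""
    return SyntheticKneeParams()


@pytest.fixture(scope="session")
def default_cohort(default_params):
    return sample_cohort(default_params)


@pytest.fixture(scope="session")
def default_long(default_cohort):
    """Full-grid simulation of the default cohort, long format."""
    return simulate_cohort(lm for lm, _ in default_cohort)


@pytest.fixture()
def canonical_specimen():
    """One noise-free right knee in canonical pose, with its ground truth."""
    from ttgsim import sample_specimen

    params = zero_noise(randomize_pose=False, side_probability=1.0)
    rng = np.random.default_rng(0)
    return sample_specimen(params, rng, specimen_id="canonical")
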