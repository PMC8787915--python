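import numpy as np
import pytest

from adprog.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default two-class cohort at a size cheap enough for unit tests."""
    return generate_cohort(CohortConfig(n_subjects=60, volume_shape=(16, 16, 16), seed=7))


@pytest.fixture(scope="session")
def noise_free_config():
    """Deterministic linear trajectories: MD slope -1/yr, FD slope -4/yr."""
    from adprog.synthetic import ClassTrajectoryParams

    return CohortConfig(
        n_subjects=40,
        volume_shape=(16, 16, 16),
        trajectory_params={
            "MD": ClassTrajectoryParams(28.0, 0.0, -1.0, 0.0, 0.0, 0.0),
            "FD": ClassTrajectoryParams(28.0, 0.0, -4.0, 0.0, 0.0, 0.0),
        },
        seed=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
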