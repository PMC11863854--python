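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


@pytest.fixture(scope="session")
def gait_cohort():
    """Small mixed-bout cohort shared by the classifier tests."""
    from armswing.synthetic import simulate_cohort

    return simulate_cohort(6, seed=2024, group="pd", state="pre", duration_s=240.0)


@pytest.fixture(scope="session")
def gait_dataset(gait_cohort):
    from armswing.pipeline import build_gait_dataset

    return build_gait_dataset(gait_cohort)


@pytest.fixture(scope="session")
def arm_dataset(gait_cohort):
    from armswing.pipeline import build_arm_dataset

    return build_arm_dataset(gait_cohort)


@pytest.fixture(scope="session")
def arm_filter_result(arm_dataset):
    from armswing.armfilter import train_arm_filter

    return train_arm_filter(arm_dataset, "logistic_lasso", seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
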