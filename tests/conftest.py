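import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced but structurally complete four-group feature cohort."""
    from sleepqeeg.synthetic import SyntheticConfig, generate_feature_cohort

    config = SyntheticConfig(
        group_sizes={"NI": 300, "INH": 90, "HNI": 40, "HI": 30}, seed=11)
    return generate_feature_cohort(config)


@pytest.fixture(scope="session")
def full_cohort():
    """Feature cohort at the default study group sizes (1386/401/133/65)."""
    from sleepqeeg.synthetic import generate_feature_cohort

    return generate_feature_cohort(seed=101)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
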