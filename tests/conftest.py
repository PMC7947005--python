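import pytest
from hypothesis import HealthCheck, settings

from quantnav import SpaceConfig, angular_profile, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    return SpaceConfig()


@pytest.fixture(scope="session")
def profile(cfg):
    return angular_profile(cfg=cfg)


@pytest.fixture(scope="session")
def smoke_cohort():
    """Tiny two-agent-per-group cohort shared across IO/pipeline tests."""
    return generate_cohort(n_per_group=2, master_seed=7)
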