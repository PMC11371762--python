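import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ohra import BandingConfig, default_hexane_profile, validate_seg


@pytest.fixture(scope="session")
def cfg():
    return BandingConfig.default()


@pytest.fixture(scope="session")
def hexane():
    return default_hexane_profile()


def make_record(**kw):
    """A typical printing-group survey row; override any field."""
    base = dict(
        group_id="g1", category="printing", n_workers=5, tenure_months=60.0,
        daily_usage=3.5, hours_per_day=8, days_per_week=6, c_twa=8.1, c_stel=24.7,
        automation="semi", ventilation="local_exhaust", first_aid=True,
        ppe_equipped=True, ppe_used=False, emergency_complete=False, health_mgmt="poor",
    )
    base.update(kw)
    return validate_seg(base)


@pytest.fixture
def record():
    return make_record()
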