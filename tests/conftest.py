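import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def vaccine_counts():
    """HIV vaccine trial: placebo 74/8198 cases vs treatment 51/8197."""
    return dict(events1=74, n1=8198, events2=51, n2=8197)


@pytest.fixture
def uniform_295():
    from rejodds import PriorSpec

    return PriorSpec.uniform_from_null(2.95)
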