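import pytest
from hypothesis import HealthCheck, settings

from snapmeta import Study

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def maxwell_original() -> Study:
    """Original study of the two-group worked example: d = 0.5, N = 80."""
    return Study.from_d(0.5, 80)


@pytest.fixture
def maxwell_replication() -> Study:
    """Replication of the worked example: d = 0.23, N = 172."""
    return Study.from_d(0.23, 172)


@pytest.fixture
def printed_original() -> Study:
    """Worked-example original from its rounded Fisher-scale summaries."""
    return Study.from_fisher(0.247, 0.114)


@pytest.fixture
def printed_replication() -> Study:
    """Worked-example replication from its rounded Fisher-scale summaries."""
    return Study.from_fisher(0.115, 0.0769)
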