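import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from feedeval import fixtures

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SUBSTRATES = ("isopod", "krill", "fish")


@pytest.fixture(scope="session")
def patterns():
    return fixtures.load_fixture("table3_patterns")


@pytest.fixture(scope="session")
def profiles():
    return fixtures.table2_profiles()


@pytest.fixture(scope="session")
def printed_scores():
    return fixtures.load_fixture("table3_scores")


@pytest.fixture(scope="session")
def growth_points():
    return fixtures.load_fixture("growth_points")


def replicates_with(mean: float, sd: float, n: int = 3) -> np.ndarray:
    """Deterministic replicates with exactly the requested mean and sd."""
    base = np.linspace(-1.0, 1.0, n)
    base = (base - base.mean()) / (base.std(ddof=1) if n > 1 else 1.0)
    return mean + sd * base
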