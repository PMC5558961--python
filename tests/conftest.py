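import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hubbell import AbundanceConfiguration, Treatment  # noqa: E402


@pytest.fixture
def small_config() -> AbundanceConfiguration:
    """A hand-sized sample: J=16, S=5."""
    return AbundanceConfiguration("toy", [8, 4, 2, 1, 1], treatment=Treatment.HEALTHY)


@pytest.fixture
def neutral_config_300() -> AbundanceConfiguration:
    """One seeded neutral community (theta=10, I=50, J=300)."""
    from hubbell import simulate_local_community

    rng = np.random.default_rng([1234, 0])
    return simulate_local_community(10.0, 50.0, 300, rng, sample_id="neutral300")


def all_partitions(J: int):
    """All integer partitions of J as abundance lists (exhaustive oracle)."""
    from sympy.utilities.iterables import partitions

    for part in partitions(J):
        yield [k for k, v in part.items() for _ in range(v)]
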