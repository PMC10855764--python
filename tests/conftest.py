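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
def camembert_table():
    """Default synthetic Camembert study (90 x 79, seeded)."""
    from cheesevoc import SyntheticStudyConfig, generate_voc_table

    return generate_voc_table(SyntheticStudyConfig(cheese="camembert", seed=42))


@pytest.fixture(scope="session")
def brie_table():
    from cheesevoc import SyntheticStudyConfig, generate_voc_table

    return generate_voc_table(SyntheticStudyConfig(cheese="brie", seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
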