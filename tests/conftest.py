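import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from osteorda import default_params, default_registry, simulate_assemblage
from osteorda.registry import Element

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_assemblage(registry):
    """Compact synthetic assemblage: 12 individuals/group, long bones only."""
    params = default_params(registry, seed=42)
    params.n_per_group = 12
    params.elements = (
        Element.HUMERUS,
        Element.RADIOULNA,
        Element.METACARPUS,
        Element.FEMUR,
        Element.TIBIA,
        Element.METATARSUS,
    )
    return simulate_assemblage(params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
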