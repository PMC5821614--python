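import numpy as np
import pytest

from confscreen import (
    AcpConfig,
    LibrarySpec,
    SplitPlan,
    generate_library,
)


@pytest.fixture(scope="session")
def signal_library():
    """Small library with a clear activity signal (for fast model tests)."""
    return generate_library(
        LibrarySpec(
            n_compounds=600,
            hit_rate=0.2,
            n_features=20,
            n_informative=6,
            effect_size=6.0,
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def noise_library():
    """Library whose labels are independent of the features."""
    return generate_library(
        LibrarySpec(n_compounds=400, hit_rate=0.1, n_features=10, effect_size=0.0, seed=7)
    )


@pytest.fixture
def plan():
    return SplitPlan(seed=0)


@pytest.fixture
def small_acp():
    return AcpConfig(n_iterations=5, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
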