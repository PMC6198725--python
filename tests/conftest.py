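import numpy as np
import pytest

from prescreenpower import generate_population


@pytest.fixture(scope="session")
def pop03():
    """Shared population with observable correlation 0.3."""
    return generate_population(0.3, size=300_000, seed=101)


@pytest.fixture(scope="session")
def pop00():
    """Shared null population (zero correlation)."""
    return generate_population(0.0, size=300_000, seed=102)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
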