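import numpy as np
import pytest

from nestedmvpa import SimParams, generate_dataset, toy_subclass_dataset


@pytest.fixture(scope="session")
def toy_data():
    """2-D dataset with 4 clear subclasses per class and no class effect."""
    return toy_subclass_dataset(seed=7)


@pytest.fixture(scope="session")
def biased_data():
    """High-dimensional dataset with strong subclass structure, no class effect."""
    return generate_dataset(
        SimParams(d=100, K=10, N=12, sigma_C=0.0, sigma_S=0.4, sigma_W=1.0, seed=42)
    )


@pytest.fixture(scope="session")
def chance_data():
    """Subclass-free, class-free data: pure noise."""
    return generate_dataset(
        SimParams(d=10, K=4, N=15, sigma_C=0.0, sigma_S=0.0, sigma_W=1.0, seed=5)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
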