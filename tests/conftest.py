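import numpy as np
import pytest

from triangulate import OperatingCharacteristics, simulate_binary, tabulate_patterns


@pytest.fixture(scope="session")
def interior_truth():
    """Interior operating characteristics used across estimation tests."""
    return OperatingCharacteristics(0.3, (0.8, 0.7, 0.6), (0.1, 0.2, 0.3))


@pytest.fixture(scope="session")
def study_truth():
    """The three-method study setting: sensitivities 0.35/0.85/0.8,
    specificities 0.85/0.35/0.8 (false-positive rates 0.15/0.65/0.2)."""
    return OperatingCharacteristics(0.3, (0.35, 0.85, 0.8), (0.15, 0.65, 0.2))


@pytest.fixture(scope="session")
def seeded_table(interior_truth):
    """Pattern table from one seeded n=2,000 dataset."""
    ds = simulate_binary(interior_truth, 2_000, seed=42)
    return tabulate_patterns(ds.matrix)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
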