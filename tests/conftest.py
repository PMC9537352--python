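import numpy as np
import pytest

from costaware import FeatureCostTable
from costaware.synthetic import FeatureBlock, SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_table():
    return FeatureCostTable(("f1", "f2", "f3"), np.array([2.0, 1.0, 1.0]))


@pytest.fixture
def recovery_spec():
    """Independent-Gaussian world with a clear budget-3 optimum {x1,x2,x3}."""
    effects = [1.2, 1.0, 0.8, 0.25, 0.2, 0.6, 0.5, 0.4]
    costs = [1, 1, 1, 1, 1, 4, 4, 4]
    blocks = tuple(
        FeatureBlock(f"x{i+1}", d, c) for i, (d, c) in enumerate(zip(effects, costs))
    )
    return SyntheticSpec(blocks, n_samples=5000, prevalence=0.2)
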