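import numpy as np
import pytest

from mctipm import ModelSet, default_truth, generate_design
from mctipm.ipm import MeshConfig
from mctipm.standardize import DEFAULT_TEMPERATURE_SCALE


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def truth_models(truth):
    """Point-estimate model set built directly from the generating truth."""
    return ModelSet.from_truth(truth)


@pytest.fixture(scope="session")
def reference_design():
    return generate_design(seed=0)


@pytest.fixture(scope="session")
def temp_std():
    """degC -> standardized temperature using the design scale."""
    return lambda c: float(DEFAULT_TEMPERATURE_SCALE.to_std(c))


@pytest.fixture
def small_mesh():
    return MeshConfig(n_classes=50)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
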