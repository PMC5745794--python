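import numpy as np
import pytest

from adaptkit.coalescent import HaplotypePanel, simulate_panel
from adaptkit.models import DemographicModel, Epoch, reference_models


@pytest.fixture(scope="session")
def constant_model():
    """One deme, constant diploid size 10,000."""
    return DemographicModel(n_demes=1, epochs=(Epoch(0.0, (10_000.0,)),))


@pytest.fixture(scope="session")
def m4():
    return reference_models()[3]


@pytest.fixture(scope="session")
def two_deme_panel(m4):
    return simulate_panel(m4, (20, 10), 50_000, seed=3)


@pytest.fixture(scope="session")
def neutral_panel(constant_model):
    return simulate_panel(constant_model, (40,), 100_000, seed=5)


@pytest.fixture
def toy_panel():
    """Four haplotypes, one SNP at frequency 2/4, sequence length 10 bp."""
    m = np.array([[1], [1], [0], [0]], dtype=np.int8)
    return HaplotypePanel(m, np.array([5]), 10, ["a", "a", "b", "b"])
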