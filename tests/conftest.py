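import numpy as np
import pytest

from niptkit.fetal_fraction import build_sim_library
from niptkit.panel import default_panel
from niptkit.simulate import PopulationModel

SEED = 0


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def pop():
    return PopulationModel()


@pytest.fixture(scope="session")
def lib150(panel):
    """MAF simulation library at the MiSeq operating point (150X, 2000 SNPs)."""
    return build_sim_library(coverage=150.0, n_snps=2000, seed=42, panel=panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
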