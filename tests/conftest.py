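import numpy as np
import pytest
from hypothesis import settings

from gpbench.datatypes import GenotypeMatrix, PhenotypeTable
from gpbench.simulate import simulate_genotypes, simulate_trait

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_dataset():
    """60 lines x 40 markers, one additive trait with strong signal."""
    G = simulate_genotypes(60, 40, seed=11)
    pheno, truth = simulate_trait(G, n_qtl=5, h2=0.8, seed=12)
    return G, pheno, truth


@pytest.fixture(scope="session")
def medium_dataset():
    """300 lines x 80 markers additive trait, h2=0.9: learnable by everything."""
    G = simulate_genotypes(300, 80, seed=21)
    pheno, truth = simulate_trait(G, n_qtl=10, h2=0.9, seed=22)
    return G, pheno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
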