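import numpy as np
import pytest

from multiherit.grm import compute_grm
from multiherit.synthetic import SimulationSpec, simulate_genotypes, simulate_pedigree


@pytest.fixture(scope="session")
def small_panel():
    """200 samples x 1500 SNPs plus their GRM: shared across estimator tests."""
    spec = SimulationSpec(n_samples=200, n_snps=1500, seed=11)
    g = simulate_genotypes(spec)
    return g, compute_grm(g)


@pytest.fixture(scope="session")
def twin_pedigree():
    """40 MZ + 40 DZ pairs + 10 sib pairs + 5 singletons."""
    return simulate_pedigree(
        SimulationSpec(pedigree_design=(40, 40, 10, 5), seed=0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
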