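import numpy as np
import pytest

from gblupga.genotypes import GenotypeMatrix
from gblupga.simulate import (
    SimulationConfig,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_trait,
)

CY_VARIANCES = dict(sigma_a2=9672.55, sigma_d2=2049.59, sigma_p2=0.0, sigma_e2=26699.68)


@pytest.fixture(scope="session")
def toy_geno():
    """2 individuals x 2 SNPs with codes [[0,1],[2,1]] (hand-checkable)."""
    return GenotypeMatrix(
        individual_ids=["a", "b"],
        snp_ids=["s1", "s2"],
        snp_chrom=np.array(["1", "1"]),
        snp_pos=np.array([100, 200]),
        codes=np.array([[0.0, 1.0], [2.0, 1.0]]),
    )


@pytest.fixture(scope="session")
def small_panel():
    """300 individuals x 800 SNPs under HWE, independent SNPs."""
    return simulate_genotypes(
        SimulationConfig(n_individuals=300, n_snps=800, n_qtl=40, seed=11)
    )


@pytest.fixture(scope="session")
def cy_dataset(small_panel):
    """CY-like trait with repeated records on the small panel."""
    cfg = SimulationConfig(n_individuals=300, n_snps=800, n_qtl=40, seed=11)
    arch = simulate_trait(small_panel, 40, **CY_VARIANCES, seed=11)
    pheno = simulate_phenotypes(small_panel, arch, cfg)
    return small_panel, arch, pheno
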