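import numpy as np
import pytest

from snpherit.mcmc import MCMCConfig, build_model_frame, run_bivariate_chain, run_univariate_chain
from snpherit.qc import GenotypeMatrix, apply_qc, center_genotypes
from snpherit.simulate import (
    MultiTraitSpec,
    SimulationConfig,
    TraitSpec,
    simulate_genotypes,
    simulate_phenotypes,
)


def make_genotypes(values, ids=None, snps=None, chroms=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return GenotypeMatrix(
        values=values,
        individual_ids=np.array(ids or [f"i{k}" for k in range(n)]),
        snp_ids=np.array(snps or [f"s{k}" for k in range(m)]),
        chromosomes=np.array(chroms or ["1"] * m),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """n=200, m=500 clean panel with one h2=0.3 trait (fast shared fixture)."""
    cfg = SimulationConfig(
        n_individuals=200, n_sires=80, n_snps=500, n_herds=5,
        herd_size_range=(20, 70), seed=42,
    )
    g = simulate_genotypes(cfg)
    spec = MultiTraitSpec(traits=[TraitSpec("t1", 0.3)])
    pheno, truth = simulate_phenotypes(g, spec, cfg)
    return g, pheno, truth


@pytest.fixture(scope="session")
def bivariate_dataset():
    """n=400, m=800 panel with two correlated traits (rg=0.6, re=-0.3)."""
    cfg = SimulationConfig(
        n_individuals=400, n_sires=150, n_snps=800, n_herds=8,
        herd_size_range=(30, 80), seed=77,
    )
    g = simulate_genotypes(cfg)
    spec = MultiTraitSpec(
        traits=[TraitSpec("t1", 0.45), TraitSpec("t2", 0.45)],
        genomic_correlations=np.array([[1.0, 0.6], [0.6, 1.0]]),
        residual_correlations=np.array([[1.0, -0.3], [-0.3, 1.0]]),
    )
    pheno, truth = simulate_phenotypes(g, spec, cfg)
    return g, pheno, truth


@pytest.fixture(scope="session")
def bivariate_chain_result(bivariate_dataset):
    """One bivariate chain shared by the MCMC and comparison tests."""
    g, pheno, truth = bivariate_dataset
    design = center_genotypes(apply_qc(g)[0])
    frame = build_model_frame(pheno, ["t1", "t2"], design)
    chain, post = run_bivariate_chain(
        frame, MCMCConfig(n_iterations=16000, burn_in=4000, thin=10, seed=5)
    )
    return chain, post


@pytest.fixture(scope="session")
def univariate_chain_result(small_dataset):
    g, pheno, truth = small_dataset
    design = center_genotypes(apply_qc(g)[0])
    frame = build_model_frame(pheno, "t1", design)
    chain, summary = run_univariate_chain(
        frame, MCMCConfig(n_iterations=8000, burn_in=2000, thin=10, seed=9)
    )
    return chain, summary
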