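import numpy as np
import pytest

from snpherit.grm import GRM, compute_grm
from snpherit.mcmc import summarize_chain
from snpherit.qc import apply_qc
from snpherit.reml import (
    REMLOptions,
    compare_bayes_reml,
    reml_bivariate,
    reml_univariate,
)
from snpherit.simulate import (
    MultiTraitSpec,
    SimulationConfig,
    TraitSpec,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="module")
def fitted_dataset():
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
    G = compute_grm(apply_qc(g)[0])
    return pheno, truth, G


class TestUnivariate:
    def test_recovers_h2_within_2_se(self, fitted_dataset):
        pheno, truth, G = fitted_dataset
        r = reml_univariate(pheno["t1"].to_numpy(), pheno["herd"], pheno["parity"], G)
        assert r.converged
        assert abs(r.h2[0] - truth.h2[0]) <= 2 * r.h2_se[0]

    def test_null_heritability_hits_boundary(self, fitted_dataset):
        pheno, _, G = fitted_dataset
        rng = np.random.default_rng(5)
        y = rng.normal(size=G.n)  # no genomic signal at all
        r = reml_univariate(y, pheno["herd"], pheno["parity"], G)
        assert r.h2[0] < 0.1

    def test_identity_grm_rejected(self, fitted_dataset):
        pheno, _, G = fitted_dataset
        eye = GRM(np.eye(G.n), 1.0, G.individual_ids)
        with pytest.raises(ValueError, match="identity"):
            reml_univariate(pheno["t1"].to_numpy(), pheno["herd"], pheno["parity"], eye)

    def test_em_iterations_never_decrease_loglik(self, fitted_dataset):
        # force pure EM: its accepted steps must be monotone uphill
        pheno, _, G = fitted_dataset
        opt = REMLOptions(n_em_start=200, max_iterations=40, tol_param=0.0)
        r = reml_univariate(pheno["t1"].to_numpy(), pheno["herd"], pheno["parity"], G, opt)
        trace = np.array(r.loglik_trace)
        assert len(trace) > 5
        assert np.all(np.diff(trace) > -1e-6)


class TestBivariate:
    def test_recovers_genomic_correlation(self, fitted_dataset):
        pheno, truth, G = fitted_dataset
        r = reml_bivariate(
            pheno["t1"].to_numpy(), pheno["t2"].to_numpy(),
            pheno["herd"], pheno["parity"], G,
        )
        assert not r.boundary_flag
        # a single fixed draw: allow 3 SEs around the realized truth
        assert abs(r.genomic_correlation - truth.genomic_correlations[0, 1]) <= 3 * max(
            r.genomic_correlation_se, 0.1
        )
        # the genomic/residual split can fluctuate, but the fitted
        # components must reproduce the observed phenotypic correlation
        cov_p = r.cov_a + r.cov_e
        var_p = r.sigma_a2 + r.sigma_e2
        implied = cov_p / np.sqrt(var_p[0] * var_p[1])
        from snpherit.pipeline import phenotypic_correlation

        observed = phenotypic_correlation(pheno, ("t1", "t2"), adjusted=True)
        assert implied == pytest.approx(observed, abs=0.1)

    def test_duplicated_trait_pins_correlation_at_boundary(self, fitted_dataset):
        pheno, _, G = fitted_dataset
        y = pheno["t1"].to_numpy()
        r = reml_bivariate(y, y.copy(), pheno["herd"], pheno["parity"], G)
        assert r.boundary_flag
        assert abs(r.genomic_correlation) >= 0.999 - 1e-9

    def test_weak_signal_small_n_produces_flagged_boundaries(self):
        # the qualitative REML failure mode: a correlated pair observed on
        # only 50 animals under-identifies the genomic correlation and the
        # estimate frequently runs to +-1, which must be flagged
        n_boundary = 0
        for seed in range(6):
            cfg = SimulationConfig(
                n_individuals=50, n_sires=25, n_snps=300, n_herds=3,
                herd_size_range=(5, 30), seed=320 + seed,
            )
            g = simulate_genotypes(cfg)
            spec = MultiTraitSpec(
                traits=[TraitSpec("a", 0.2), TraitSpec("b", 0.2)],
                genomic_correlations=np.array([[1.0, 0.6], [0.6, 1.0]]),
                residual_correlations=np.array([[1.0, 0.3], [0.3, 1.0]]),
            )
            pheno, _ = simulate_phenotypes(g, spec, cfg)
            G = compute_grm(apply_qc(g)[0])
            r = reml_bivariate(
                pheno["a"].to_numpy(), pheno["b"].to_numpy(),
                pheno["herd"], pheno["parity"], G,
            )
            if r.boundary_flag:
                n_boundary += 1
                assert abs(r.genomic_correlation) >= 0.999 - 1e-9
        assert n_boundary >= 1

    def test_mismatched_lengths_rejected(self, fitted_dataset):
        pheno, _, G = fitted_dataset
        with pytest.raises(ValueError):
            reml_bivariate(
                pheno["t1"].to_numpy(), pheno["t2"].to_numpy()[:-1],
                pheno["herd"], pheno["parity"], G,
            )


class TestComparison:
    def test_single_pair_table(self, bivariate_chain_result, fitted_dataset):
        _, post = bivariate_chain_result
        pheno, _, G = fitted_dataset
        r = reml_bivariate(
            pheno["t1"].to_numpy(), pheno["t2"].to_numpy(),
            pheno["herd"], pheno["parity"], G,
        )
        table = compare_bayes_reml([post], [r], [("t1", "t2")], [0.5])
        assert len(table) == 1
        row = table.iloc[0]
        assert row["abs_difference"] == pytest.approx(
            abs(post.genomic_correlation_mean - r.genomic_correlation)
        )
        assert row["phenotypic_correlation"] == 0.5

    def test_boundary_rows_excluded_from_agreement(self, bivariate_chain_result, fitted_dataset):
        _, post = bivariate_chain_result
        pheno, _, G = fitted_dataset
        good = reml_bivariate(
            pheno["t1"].to_numpy(), pheno["t2"].to_numpy(),
            pheno["herd"], pheno["parity"], G,
        )
        y = pheno["t1"].to_numpy()
        bad = reml_bivariate(y, y.copy(), pheno["herd"], pheno["parity"], G)
        table = compare_bayes_reml([post, post], [good, bad])
        assert table["reml_boundary"].tolist() == [False, True]
        assert table.attrs["n_boundary"] == 1
        # the flagged row is present in the table but not in the statistic
        assert table.attrs["agreement"] == pytest.approx(
            abs(post.genomic_correlation_mean - good.genomic_correlation)
        )

    def test_mismatched_lists_rejected(self, bivariate_chain_result):
        _, post = bivariate_chain_result
        with pytest.raises(ValueError):
            compare_bayes_reml([post], [])

    def test_bayes_never_sits_on_the_boundary(self, bivariate_chain_result):
        # the Bayesian posterior mean stays inside (-1, 1) even where REML
        # would pin at +-1
        _, post = bivariate_chain_result
        assert abs(post.genomic_correlation_mean) < 0.999
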