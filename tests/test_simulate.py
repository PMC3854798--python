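import numpy as np
import pytest

from snpherit.simulate import (
    ConfigurationError,
    MultiTraitSpec,
    SimulationConfig,
    TraitSpec,
    make_study_like_dataset,
    simulate_genotypes,
    simulate_phenotypes,
    study_trait_spec,
)


def small_config(**kw):
    base = dict(
        n_individuals=50, n_sires=20, n_snps=100, n_herds=4,
        herd_size_range=(5, 30), seed=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateGenotypes:
    def test_allele_counts_in_domain(self):
        g = simulate_genotypes(small_config())
        assert np.isin(g.values, (0.0, 1.0, 2.0)).all()

    def test_same_seed_is_bit_identical(self):
        a = simulate_genotypes(small_config(seed=3, missing_rate=0.05))
        b = simulate_genotypes(small_config(seed=3, missing_rate=0.05))
        assert np.array_equal(a.values, b.values, equal_nan=True)
        c = simulate_genotypes(small_config(seed=4, missing_rate=0.05))
        assert not np.array_equal(a.values, c.values, equal_nan=True)

    def test_missing_rate(self):
        g = simulate_genotypes(small_config(n_individuals=200, n_snps=500, missing_rate=0.1, herd_size_range=(5, 100)))
        rate = np.isnan(g.values).mean()
        assert abs(rate - 0.1) < 0.01

    def test_monomorphic_fraction(self):
        # expected count 100 of 1000; binomial-ish tolerance over the draw
        g = simulate_genotypes(
            small_config(n_individuals=200, n_snps=1000, monomorphic_rate=0.1,
                         herd_size_range=(5, 100))
        )
        n_mono = int((np.nanvar(g.values, axis=0) == 0.0).sum())
        assert 80 <= n_mono  # >= requested fixed loci (sampling may fix a few more)
        assert n_mono <= 140

    def test_low_maf_fraction(self):
        g = simulate_genotypes(small_config(n_individuals=500, n_snps=1000, low_maf_rate=0.1, herd_size_range=(5, 200)))
        p = np.nanmean(g.values, axis=0) / 2
        maf = np.minimum(p, 1 - p)
        assert 60 <= int(((maf < 0.01) & (maf > 0)).sum() + (maf == 0).sum()) <= 160

    def test_chromosome_blocks(self):
        g = simulate_genotypes(small_config(n_snps=100, n_chromosomes=4))
        labels, counts = np.unique(g.chromosomes, return_counts=True)
        assert len(labels) == 4 and counts.sum() == 100
        # contiguity: each label occupies one run of consecutive columns
        changes = (g.chromosomes[1:] != g.chromosomes[:-1]).sum()
        assert changes == 3

    def test_invalid_rates_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(missing_rate=1.5)
        with pytest.raises(ConfigurationError):
            small_config(n_individuals=0)
        with pytest.raises(ConfigurationError):
            small_config(n_herds=2, herd_size_range=(3, 5))  # cannot sum to 50


class TestSimulatePhenotypes:
    def test_zero_heritability_trait_has_no_genomic_component(self):
        cfg = small_config()
        g = simulate_genotypes(cfg)
        spec = MultiTraitSpec(traits=[TraitSpec("flat", 0.0)])
        pheno, truth = simulate_phenotypes(g, spec, cfg)
        assert truth.sigma_u2[0] == 0.0
        assert truth.h2[0] == 0.0
        assert np.all(truth.snp_effects == 0.0)

    def test_perfect_genomic_correlation_gives_identical_effects(self):
        cfg = small_config()
        g = simulate_genotypes(cfg)
        spec = MultiTraitSpec(
            traits=[TraitSpec("a", 0.3), TraitSpec("b", 0.3)],
            genomic_correlations=np.array([[1.0, 1.0], [1.0, 1.0]]),
        )
        pheno, truth = simulate_phenotypes(g, spec, cfg)
        np.testing.assert_allclose(truth.snp_effects[:, 0], truth.snp_effects[:, 1], atol=1e-12)

    def test_recorded_h2_identity_is_exact(self):
        cfg = small_config()
        g = simulate_genotypes(cfg)
        pheno, truth = simulate_phenotypes(g, MultiTraitSpec(traits=[TraitSpec("t", 0.4)]), cfg)
        np.testing.assert_allclose(
            truth.h2, truth.sigma_u2 / (truth.sigma_u2 + truth.sigma_e2), rtol=0, atol=0
        )
        # and the recorded components are the moments of the emitted vectors
        np.testing.assert_allclose(truth.sigma_u2[0], truth.genomic_values[:, 0].var())

    def test_realized_h2_near_target_at_scale(self):
        cfg = SimulationConfig(
            n_individuals=500, n_sires=200, n_snps=2000, n_herds=10,
            herd_size_range=(30, 70), seed=9,
        )
        g = simulate_genotypes(cfg)
        pheno, truth = simulate_phenotypes(g, MultiTraitSpec(traits=[TraitSpec("t", 0.3)]), cfg)
        assert abs(truth.h2[0] - 0.3) < 0.08

    def test_var_zu_matches_target_across_replicates(self):
        # mean realized Var(Zu) over 50 replicates within 3 SE of the target
        target = 0.3
        vals = []
        for rep in range(50):
            cfg = SimulationConfig(
                n_individuals=500, n_sires=200, n_snps=300, n_herds=10,
                herd_size_range=(30, 70), seed=1000 + rep,
            )
            g = simulate_genotypes(cfg)
            _, truth = simulate_phenotypes(g, MultiTraitSpec(traits=[TraitSpec("t", target)]), cfg)
            vals.append(truth.sigma_u2[0])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - target) < 3 * se

    def test_non_psd_correlations_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ConfigurationError):
            MultiTraitSpec(traits=[TraitSpec("a", 0.2), TraitSpec("b", 0.2)], genomic_correlations=bad)


class TestStudyPreset:
    @pytest.fixture(scope="class")
    def preset(self):
        return make_study_like_dataset(seed=1)

    def test_row_count(self, preset):
        _, pheno, _ = preset
        assert len(pheno) == 371

    def test_herd_structure(self, preset):
        _, pheno, _ = preset
        sizes = pheno["herd"].value_counts()
        assert pheno["herd"].nunique() == 19
        assert sizes.min() >= 3 and sizes.max() <= 24
        assert sizes.sum() == 371

    def test_parity_levels(self, preset):
        _, pheno, _ = preset
        assert set(pheno["parity"].unique()) <= {1, 2, 3}

    def test_trait_ranges_span_study_tables(self, preset):
        _, _, truth = preset
        assert truth.target_h2.min() == pytest.approx(0.07)
        assert truth.target_h2.max() == pytest.approx(0.35)
        off = truth.target_genomic_correlations[np.triu_indices(6, 1)]
        assert off.min() == pytest.approx(-0.6, abs=0.01)
        assert off.max() == pytest.approx(0.91, abs=0.01)

    def test_sire_count(self, preset):
        _, pheno, _ = preset
        assert pheno["sire_id"].nunique() <= 200

    def test_spec_correlations_are_psd(self):
        spec = study_trait_spec()
        assert np.linalg.eigvalsh(spec.genomic_correlations).min() > -1e-10
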