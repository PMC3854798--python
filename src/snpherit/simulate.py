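"""Synthetic genotype/phenotype generator emulating a half-sib dairy design.

The generator mirrors the sampling structure of a field study on Danish
Holstein milk composition: a few hundred cows descending from many sires
(so families are mostly tiny), grouped into herds of widely varying size,
with parities 1-3 and a genome-wide biallelic SNP panel. Genotypes are
gene-dropped from a sampled sire and an unrelated dam under a per-SNP
allele-frequency law, which gives the correct half-sib relatedness
(expected genomic relationship 0.25 between paternal half-sibs) without
modelling linkage. Phenotypes follow the additive SNP-regression model

    y = mu + herd + parity + Z u + e

with per-SNP effects drawn jointly across traits so that the realized
SNP-explained variance Var(Zu) matches a target heritability, and
residuals drawn with a chosen residual correlation structure. The
generating parameters and the *realized* variance components are recorded
so recovery tests can compare estimates against exact truths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "TraitSpec",
    "MultiTraitSpec",
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "make_study_like_dataset",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_individuals: int = 371
    n_sires: int = 200
    n_snps: int = 2000
    n_chromosomes: int = 5
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    n_herds: int = 19
    herd_size_range: tuple[int, int] = (3, 24)
    parity_levels: int = 3
    missing_rate: float = 0.0
    monomorphic_rate: float = 0.0
    low_maf_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sires > self.n_individuals and self.n_individuals > 0:
            # more potential sires than cows is fine; each cow samples one
            pass
        for name in ("n_individuals", "n_sires", "n_snps", "n_chromosomes", "n_herds", "parity_levels"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("missing_rate", "monomorphic_rate", "low_maf_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1), got {v}")
        lo, hi = self.herd_size_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("invalid herd_size_range")
        if not self.n_herds * lo <= self.n_individuals <= self.n_herds * hi:
            raise ConfigurationError(
                "herd sizes in the given range cannot sum to n_individuals"
            )
        a, b = self.allele_freq_range
        if not 0.0 < a <= b < 1.0:
            raise ConfigurationError("allele_freq_range must satisfy 0 < lo <= hi < 1")


@dataclass
class TraitSpec:
    name: str
    true_h2: float
    mean: float = 0.0
    herd_effect_sd: float = 0.25
    parity_effects: tuple[float, float, float] = (0.0, 0.1, 0.2)

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_h2 <= 1.0:
            raise ConfigurationError(f"true_h2 must lie in [0, 1], got {self.true_h2}")


@dataclass
class MultiTraitSpec:
    traits: list[TraitSpec]
    genomic_correlations: np.ndarray | None = None
    residual_correlations: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = len(self.traits)
        if self.genomic_correlations is None:
            self.genomic_correlations = np.eye(t)
        if self.residual_correlations is None:
            self.residual_correlations = np.eye(t)
        for name in ("genomic_correlations", "residual_correlations"):
            c = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, c)
            if c.shape != (t, t):
                raise ConfigurationError(f"{name} must be {t}x{t}")
            if not np.allclose(c, c.T):
                raise ConfigurationError(f"{name} must be symmetric")
            if not np.allclose(np.diag(c), 1.0):
                raise ConfigurationError(f"{name} must have a unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-8:
                raise ConfigurationError(f"{name} is not positive semi-definite")

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.traits]


@dataclass
class SimulationTruth:
    """Generating parameters plus realized variance components.

    ``h2`` is computed from the emitted components as
    Var(Zu) / (Var(Zu) + Var(e)) using the population (n-denominator)
    variance, so it holds exactly for the generated data set.
    """

    trait_names: list[str]
    target_h2: np.ndarray
    sigma_u2: np.ndarray          # realized Var(Zu) per trait
    sigma_e2: np.ndarray          # realized residual variance per trait
    h2: np.ndarray                # realized heritability per trait
    genomic_correlations: np.ndarray   # realized corr of the Zu columns
    residual_correlations: np.ndarray  # realized corr of the residual columns
    target_genomic_correlations: np.ndarray
    target_residual_correlations: np.ndarray
    snp_effects: np.ndarray       # m x T generating effect vectors
    herd_effects: np.ndarray      # herds x T
    parity_effects: np.ndarray    # parities x T
    genomic_values: np.ndarray = field(repr=False, default=None)  # n x T, Zu

    def to_json(self, path: str) -> None:
        payload = {
            "trait_names": self.trait_names,
            "target_h2": self.target_h2.tolist(),
            "sigma_u2": self.sigma_u2.tolist(),
            "sigma_e2": self.sigma_e2.tolist(),
            "h2": self.h2.tolist(),
            "genomic_correlations": self.genomic_correlations.tolist(),
            "residual_correlations": self.residual_correlations.tolist(),
            "target_genomic_correlations": self.target_genomic_correlations.tolist(),
            "target_residual_correlations": self.target_residual_correlations.tolist(),
            "herd_effects": self.herd_effects.tolist(),
            "parity_effects": self.parity_effects.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _draw_allele_freqs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-SNP frequency of the counted allele, with monomorphic / low-MAF
    fractions placed at the start-of-array positions (positions are then
    shuffled so QC tests cannot rely on ordering)."""
    m = config.n_snps
    lo, hi = config.allele_freq_range
    p = rng.uniform(lo, hi, size=m)
    n_mono = int(round(config.monomorphic_rate * m))
    n_low = int(round(config.low_maf_rate * m))
    if n_mono + n_low > m:
        raise ConfigurationError("monomorphic_rate + low_maf_rate exceed 1")
    p[:n_mono] = rng.choice([0.0, 1.0], size=n_mono)
    p[n_mono : n_mono + n_low] = rng.uniform(0.0005, 0.0099, size=n_low)
    rng.shuffle(p)
    return p


def _gene_drop(p: np.ndarray, sire_of: np.ndarray, n_sires: int, rng: np.random.Generator) -> np.ndarray:
    """Cow genotypes: one allele transmitted by the sire, one drawn from an
    unrelated dam at the population frequency."""
    m = p.size
    sire_haplo = rng.binomial(1, p, size=(n_sires, 2, m)).astype(np.int8)
    pick = rng.integers(0, 2, size=(sire_of.size, m))
    paternal = sire_haplo[sire_of[:, None], pick, np.arange(m)[None, :]]
    maternal = rng.binomial(1, p, size=(sire_of.size, m)).astype(np.int8)
    return (paternal + maternal).astype(float)


def _herd_sizes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Herd sizes summing exactly to n_individuals with every size inside the
    allowed range, by multinomial rejection."""
    lo, hi = config.herd_size_range
    probs = np.full(config.n_herds, 1.0 / config.n_herds)
    for _ in range(100_000):
        sizes = rng.multinomial(config.n_individuals, probs)
        if sizes.min() >= lo and sizes.max() <= hi:
            return sizes
    raise ConfigurationError("could not draw herd sizes in range; widen herd_size_range")


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Gene-drop a half-sib genotype panel.

    Returns allele-count calls in {0,1,2} with missing entries (``nan``)
    at ``missing_rate``, a ``monomorphic_rate`` fraction of fixed loci and
    a ``low_maf_rate`` fraction with MAF below 1%, spread over
    ``n_chromosomes`` contiguous blocks.
    """
    rng = np.random.default_rng(config.seed)
    p = _draw_allele_freqs(config, rng)
    sire_of = rng.integers(0, config.n_sires, size=config.n_individuals)
    values = _gene_drop(p, sire_of, config.n_sires, rng)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = np.nan
    n, m = values.shape
    chrom_of = np.repeat(
        np.arange(1, config.n_chromosomes + 1),
        np.diff(np.linspace(0, m, config.n_chromosomes + 1).astype(int)),
    ).astype(str)
    gm = GenotypeMatrix(
        values=values,
        individual_ids=np.array([f"cow{i:04d}" for i in range(n)]),
        snp_ids=np.array([f"snp{j:05d}" for j in range(m)]),
        chromosomes=chrom_of,
    )
    gm.sire_of = np.array([f"sire{s:03d}" for s in sire_of])  # carried for phenotypes
    return gm


def _centered(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed, 2p-centered copy; monomorphic columns come out all-zero."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(values, axis=0) / 2.0
    Z = values - 2.0 * p
    Z[~np.isfinite(Z)] = 0.0
    return Z, p


def _sample_correlated(cov: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` rows from N(0, cov); tolerates PSD-singular covariances."""
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    A = v * np.sqrt(w)
    return rng.standard_normal((size, cov.shape[0])) @ A.T


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    spec: MultiTraitSpec,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate trait values on an existing genotype panel.

    Phenotypic variance is on the unit scale: the target SNP-explained
    variance for a trait equals its ``true_h2`` and the residual variance
    ``1 - true_h2``. Per-SNP effect vectors are drawn jointly across
    traits from N(0, C) with C scaled by sigma_a^2 / sum 2p(1-p), so the
    expected Var(Zu) hits the target; realized values are what the truth
    records.
    """
    if genotypes.n_individuals == 0 or genotypes.n_snps == 0:
        raise ConfigurationError("empty genotype matrix")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7351]))
    T = len(spec.traits)
    n, m = genotypes.values.shape

    Z, p = _centered(genotypes.values)
    het = 2.0 * p * (1.0 - p)
    het[~np.isfinite(het)] = 0.0
    denom = het.sum()
    if denom <= 0:
        raise ConfigurationError("no polymorphic SNPs to carry genetic signal")

    target_sa2 = np.array([t.true_h2 for t in spec.traits])
    target_se2 = 1.0 - target_sa2
    per_snp_sd = np.sqrt(target_sa2 / denom)
    effect_cov = spec.genomic_correlations * np.outer(per_snp_sd, per_snp_sd)
    u = _sample_correlated(effect_cov, m, rng)  # m x T
    g = Z @ u  # n x T genomic values

    resid_cov = spec.residual_correlations * np.outer(np.sqrt(target_se2), np.sqrt(target_se2))
    e = _sample_correlated(resid_cov, n, rng)

    herd_sizes = _herd_sizes(config, rng)
    herd = np.repeat(np.arange(config.n_herds), herd_sizes)
    rng.shuffle(herd)
    parity = rng.integers(1, config.parity_levels + 1, size=n)

    herd_eff = np.column_stack(
        [rng.normal(0.0, t.herd_effect_sd, size=config.n_herds) for t in spec.traits]
    )
    parity_eff = np.column_stack(
        [np.asarray(t.parity_effects, dtype=float)[: config.parity_levels] for t in spec.traits]
    )
    mean = np.array([t.mean for t in spec.traits])

    y = mean + herd_eff[herd] + parity_eff[parity - 1] + g + e

    sire_ids = getattr(genotypes, "sire_of", np.array(["sire000"] * n))
    pheno = pd.DataFrame(
        {
            "id": genotypes.individual_ids,
            "sire_id": sire_ids,
            "herd": np.array([f"herd{h:02d}" for h in herd]),
            "parity": parity,
        }
    )
    for k, t in enumerate(spec.traits):
        pheno[t.name] = y[:, k]

    var_g = g.var(axis=0)  # population (n) denominator, matching the estimators
    var_e = e.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr_g = np.corrcoef(g.T) if T > 1 else np.ones((1, 1))
        corr_e = np.corrcoef(e.T) if T > 1 else np.ones((1, 1))
    corr_g = np.nan_to_num(np.atleast_2d(corr_g), nan=0.0)
    np.fill_diagonal(corr_g, 1.0)
    truth = SimulationTruth(
        trait_names=spec.names,
        target_h2=target_sa2,
        sigma_u2=var_g,
        sigma_e2=var_e,
        h2=var_g / (var_g + var_e),
        genomic_correlations=corr_g,
        residual_correlations=np.atleast_2d(corr_e),
        target_genomic_correlations=spec.genomic_correlations,
        target_residual_correlations=spec.residual_correlations,
        snp_effects=u,
        herd_effects=herd_eff,
        parity_effects=parity_eff,
        genomic_values=g,
    )
    return pheno, truth


# angles on a circle give a rank-2 correlation matrix; with no gap below
# 25 deg and a full span of 127 deg the entries cover
# cos(127 deg) = -0.60 ... cos(25 deg) = 0.91, the ranges the study reported
_STUDY_ANGLES_DEG = np.array([0.0, 25.0, 51.0, 77.0, 102.0, 127.0])
_STUDY_H2 = np.array([0.35, 0.30, 0.25, 0.19, 0.14, 0.07])


def study_trait_spec() -> MultiTraitSpec:
    """Six traits with heritabilities spanning 0.07-0.35 and genomic
    correlations spanning [-0.60, 0.91], emulating the ranges of the
    milk fatty-acid study."""
    ang = np.deg2rad(_STUDY_ANGLES_DEG)
    gcorr = np.cos(ang[:, None] - ang[None, :])
    rcorr_angles = np.deg2rad(np.array([0.0, 30.0, 50.0, 75.0, 100.0, 120.0]))
    rcorr = np.cos(rcorr_angles[:, None] - rcorr_angles[None, :])
    traits = [
        TraitSpec(name=f"trait{k + 1}", true_h2=h2, mean=5.0 + k)
        for k, h2 in enumerate(_STUDY_H2)
    ]
    return MultiTraitSpec(traits=traits, genomic_correlations=gcorr, residual_correlations=rcorr)


def make_study_like_dataset(seed: int) -> tuple[GenotypeMatrix, pd.DataFrame, SimulationTruth]:
    """One-call preset mirroring the field-study design: 371 cows from 200
    sires in 19 herds of 3-24 cows, parities 1-3, 2000 SNPs on 5
    chromosomes with a little missingness and a few QC-relevant loci."""
    config = SimulationConfig(
        n_individuals=371,
        n_sires=200,
        n_snps=2000,
        n_chromosomes=5,
        n_herds=19,
        herd_size_range=(3, 24),
        parity_levels=3,
        missing_rate=0.02,
        monomorphic_rate=0.01,
        low_maf_rate=0.01,
        seed=seed,
    )
    genotypes = simulate_genotypes(config)
    pheno, truth = simulate_phenotypes(genotypes, study_trait_spec(), config)
    return genotypes, pheno, truth
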