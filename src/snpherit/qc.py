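"""Marker and individual quality control, and the centered SNP design matrix.

Filters mirror common genotyping-panel QC: individuals below a minimum
call rate are dropped first, then loci below a locus call rate, then loci
with minor allele frequency (MAF) under a threshold (monomorphic loci are
a special case of the MAF rule and are reported separately). The
surviving allele counts are mean-imputed and centered on twice the
observed allele frequency, which is the covariate coding the Bayesian
SNP-regression model expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "QCThresholds",
    "QCReport",
    "CenteredDesign",
    "QCError",
    "apply_qc",
    "center_genotypes",
]


class QCError(ValueError):
    """Raised when filtering removes every individual or every locus."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele counts in {0,1,2}; ``nan`` marks missing calls."""

    values: np.ndarray
    individual_ids: np.ndarray
    snp_ids: np.ndarray
    chromosomes: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        n, m = self.values.shape
        if len(self.individual_ids) != n or len(self.snp_ids) != m:
            raise ValueError("id lengths do not match the genotype matrix")
        if len(self.chromosomes) != m:
            raise ValueError("need one chromosome label per SNP")
        if len(set(self.individual_ids)) != n or len(set(self.snp_ids)) != m:
            raise ValueError("individual and SNP ids must be unique")
        obs = self.values[np.isfinite(self.values)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing genotype entries must be 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def allele_freqs(self) -> np.ndarray:
        """Observed frequency of the counted (second) allele per SNP."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def subset(self, rows: np.ndarray | None = None, cols: np.ndarray | None = None) -> "GenotypeMatrix":
        rows = np.arange(self.n_individuals) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_snps) if cols is None else np.asarray(cols)
        return GenotypeMatrix(
            values=self.values[np.ix_(rows, cols)],
            individual_ids=self.individual_ids[rows],
            snp_ids=self.snp_ids[cols],
            chromosomes=self.chromosomes[cols],
        )


@dataclass
class QCThresholds:
    min_individual_call_rate: float = 0.80
    min_locus_call_rate: float = 0.95
    min_maf: float = 0.01
    min_gencall: float = 0.65  # only applied when a score matrix is supplied

    def __post_init__(self) -> None:
        for name in ("min_individual_call_rate", "min_locus_call_rate", "min_maf", "min_gencall"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QCReport:
    individuals_removed: list = field(default_factory=list)  # (id, reason)
    snps_removed: list = field(default_factory=list)  # (id, reason)
    n_individuals_before: int = 0
    n_individuals_after: int = 0
    n_snps_before: int = 0
    n_snps_after: int = 0

    def validate(self) -> None:
        assert self.n_individuals_before - len(self.individuals_removed) == self.n_individuals_after
        assert self.n_snps_before - len(self.snps_removed) == self.n_snps_after

    def to_dict(self) -> dict:
        return {
            "individuals_removed": [{"id": i, "reason": r} for i, r in self.individuals_removed],
            "snps_removed": [{"id": s, "reason": r} for s, r in self.snps_removed],
            "n_individuals_before": self.n_individuals_before,
            "n_individuals_after": self.n_individuals_after,
            "n_snps_before": self.n_snps_before,
            "n_snps_after": self.n_snps_after,
        }


@dataclass
class CenteredDesign:
    """Mean-imputed, frequency-centered SNP covariates Z with its VanRaden denominator."""

    Z: np.ndarray
    allele_freqs: np.ndarray
    scaling_denominator: float
    individual_ids: np.ndarray
    snp_ids: np.ndarray


def apply_qc(
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    gencall_scores: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter individuals on call rate, then loci on call rate and MAF.

    Call rates for loci and MAF are recomputed after the individual filter,
    so a locus is judged on the animals that actually remain. When
    ``gencall_scores`` (same shape as the genotypes) is given, calls below
    ``thresholds.min_gencall`` are first set missing and individuals whose
    average score falls below the same threshold are removed.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    if genotypes.n_individuals == 0 or genotypes.n_snps == 0:
        raise QCError("empty genotype matrix")

    report = QCReport(
        n_individuals_before=genotypes.n_individuals,
        n_snps_before=genotypes.n_snps,
    )

    values = genotypes.values.copy()
    low_score_individuals: set[str] = set()
    if gencall_scores is not None:
        scores = np.asarray(gencall_scores, dtype=float)
        if scores.shape != values.shape:
            raise ValueError("gencall score matrix must match the genotype shape")
        values[scores < thresholds.min_gencall] = np.nan
        mean_scores = np.nanmean(scores, axis=1)
        low_score_individuals = {
            genotypes.individual_ids[i]
            for i in np.where(mean_scores < thresholds.min_gencall)[0]
        }
    work = GenotypeMatrix(values, genotypes.individual_ids, genotypes.snp_ids, genotypes.chromosomes)

    # the three filters are applied in order, and the pass repeats until a
    # fixed point: removing loci can push an individual's call rate below
    # its threshold, and removing individuals can change locus statistics,
    # so a single sweep would not be idempotent
    changed = True
    first_pass = True
    while changed:
        changed = False

        # 1. individual call rate (plus the optional GenCall average-score rule)
        ind_call = np.isfinite(work.values).mean(axis=1)
        keep_ind = np.ones(work.n_individuals, dtype=bool)
        for i in range(work.n_individuals):
            if first_pass and work.individual_ids[i] in low_score_individuals:
                keep_ind[i] = False
                report.individuals_removed.append((work.individual_ids[i], "gencall"))
            elif ind_call[i] < thresholds.min_individual_call_rate:
                keep_ind[i] = False
                report.individuals_removed.append((work.individual_ids[i], "call_rate"))
        if not keep_ind.any():
            raise QCError("individual call-rate filter removed every individual")
        if not keep_ind.all():
            work = work.subset(rows=np.where(keep_ind)[0])
            changed = True

        # 2. locus call rate, recomputed on the remaining individuals
        locus_call = np.isfinite(work.values).mean(axis=0)
        keep_locus = locus_call >= thresholds.min_locus_call_rate
        for j in np.where(~keep_locus)[0]:
            report.snps_removed.append((work.snp_ids[j], "call_rate"))
        if not keep_locus.any():
            raise QCError("locus call-rate filter removed every SNP")
        if not keep_locus.all():
            work = work.subset(cols=np.where(keep_locus)[0])
            changed = True

        # 3. MAF; a zero MAF means the locus is monomorphic
        maf = work.maf()
        keep_maf = maf >= thresholds.min_maf
        for j in np.where(~keep_maf)[0]:
            reason = "monomorphic" if maf[j] == 0.0 else "MAF"
            report.snps_removed.append((work.snp_ids[j], reason))
        if not keep_maf.any():
            raise QCError("MAF filter removed every SNP")
        if not keep_maf.all():
            work = work.subset(cols=np.where(keep_maf)[0])
            changed = True
        first_pass = False

    report.n_individuals_after = work.n_individuals
    report.n_snps_after = work.n_snps
    report.validate()
    return work, report


def center_genotypes(genotypes: GenotypeMatrix) -> CenteredDesign:
    """Mean-impute missing calls and center each SNP column on 2p.

    Requires polymorphic input: a monomorphic column has no usable
    frequency and should have been removed by :func:`apply_qc`.
    """
    p = genotypes.allele_freqs()
    if np.any(~np.isfinite(p)) or np.any((p <= 0.0) | (p >= 1.0)):
        bad = genotypes.snp_ids[~np.isfinite(p) | (p <= 0.0) | (p >= 1.0)]
        raise ValueError(f"monomorphic or all-missing SNP column(s): {list(bad[:5])} ...")
    Z = genotypes.values - 2.0 * p
    Z[~np.isfinite(Z)] = 0.0  # mean imputation: imputed calls sit at the column mean
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    return CenteredDesign(
        Z=Z,
        allele_freqs=p,
        scaling_denominator=denom,
        individual_ids=genotypes.individual_ids,
        snp_ids=genotypes.snp_ids,
    )
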