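"""Genomic relationship matrix (VanRaden method 1).

G = ZZ' / [2 * sum_i p_i (1 - p_i)], with M coded -1/0/1 for the two
homozygotes and the heterozygote, P holding 2(p_i - 0.5) per column, and
Z = M - P. Observed sample allele frequencies are used. The matrix can
be assembled per chromosome and recombined exactly by weighting each
chromosome's matrix with its own scaling denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import GenotypeMatrix

__all__ = ["GRM", "compute_grm", "compute_grm_per_chromosome", "combine_chromosome_grms"]


@dataclass
class GRM:
    values: np.ndarray
    scaling_denominator: float
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("GRM must be square")
        if len(self.individual_ids) != self.values.shape[0]:
            raise ValueError("id count must match matrix order")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def with_ridge(self, ridge: float = 1e-6) -> "GRM":
        """Return a copy with ``ridge`` added to the diagonal (stabilises
        inversion in REML); the caller is expected to log its use."""
        return GRM(self.values + ridge * np.eye(self.n), self.scaling_denominator, self.individual_ids)

    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame(self.values, index=self.individual_ids, columns=self.individual_ids)
        with open(path, "w") as fh:
            fh.write(f"#scaling_denominator\t{self.scaling_denominator!r}\n")
            df.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str) -> "GRM":
        with open(path) as fh:
            first = fh.readline()
            denom = float(first.split("\t")[1]) if first.startswith("#") else np.nan
            if not first.startswith("#"):
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(df.to_numpy(), denom, np.array(df.index, dtype=str))

    def to_npz(self, path: str) -> None:
        np.savez_compressed(
            path, values=self.values, denom=self.scaling_denominator, ids=self.individual_ids
        )

    @classmethod
    def from_npz(cls, path: str) -> "GRM":
        d = np.load(path, allow_pickle=False)
        return cls(d["values"], float(d["denom"]), d["ids"].astype(str))


def compute_grm(genotypes: GenotypeMatrix) -> GRM:
    """VanRaden method-1 GRM from QC'd genotypes.

    Missing calls are imputed at the column mean (their centered covariate
    is zero, so they contribute no relationship signal). Monomorphic
    columns are rejected: QC must run first.
    """
    if genotypes.n_individuals == 0 or genotypes.n_snps == 0:
        raise ValueError("empty genotype matrix")
    p = genotypes.allele_freqs()
    if np.any(~np.isfinite(p)) or np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("monomorphic SNP column in GRM input; run QC first")
    M = genotypes.values - 1.0  # -1 / 0 / 1 coding
    P = 2.0 * (p - 0.5)
    Z = M - P
    Z[~np.isfinite(Z)] = 0.0
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)  # exact symmetry despite BLAS rounding
    return GRM(G, denom, genotypes.individual_ids)


def compute_grm_per_chromosome(genotypes: GenotypeMatrix) -> dict[str, GRM]:
    out: dict[str, GRM] = {}
    for chrom in pd.unique(genotypes.chromosomes):
        cols = np.where(genotypes.chromosomes == chrom)[0]
        out[str(chrom)] = compute_grm(genotypes.subset(cols=cols))
    return out


def combine_chromosome_grms(per_chromosome: list[GRM]) -> GRM:
    """Denominator-weighted combination; equals the whole-genome GRM exactly.

    G = sum_c d_c G_c / sum_c d_c, because each d_c G_c is that
    chromosome's un-normalised cross-product Z_c Z_c'. Chromosomes with a
    zero denominator carry no information and are excluded from both sums.
    """
    if not per_chromosome:
        raise ValueError("no GRMs to combine")
    ids = per_chromosome[0].individual_ids
    for g in per_chromosome[1:]:
        if not np.array_equal(g.individual_ids, ids):
            raise ValueError("per-chromosome GRMs cover different individuals")
    useful = [g for g in per_chromosome if g.scaling_denominator > 0.0]
    if not useful:
        raise ValueError("all chromosome denominators are zero")
    total = sum(g.scaling_denominator for g in useful)
    combined = sum(g.scaling_denominator * g.values for g in useful) / total
    return GRM(combined, total, ids)
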