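"""Text I/O for genotype and phenotype tables.

Two genotype dialects are supported:

* a simple TSV with rows = individuals, columns = SNPs, entries 0/1/2
  (allele counts of the second allele) and ``NA`` for missing calls; the
  first column holds the individual id and the header the SNP ids;
* PLINK-style ``.ped``/``.map`` text, where each SNP is written as a pair
  of allele letters (``A``/``B``, ``0 0`` for missing).

Phenotypes travel as TSV with columns ``id``, ``sire_id``, ``herd``,
``parity`` followed by one column per trait.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .qc import GenotypeMatrix

__all__ = [
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_plink",
    "read_plink",
    "write_phenotypes",
    "read_phenotypes",
]


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(
        genotypes.values,
        index=pd.Index(genotypes.individual_ids, name="id"),
        columns=genotypes.snp_ids,
    )
    with open(path, "w") as fh:
        # comment line keeps the chromosome assignment round-trippable
        fh.write("#chrom\t" + "\t".join(str(c) for c in genotypes.chromosomes) + "\n")
        df.to_csv(fh, sep="\t", na_rep="NA", float_format="%.0f")


def read_genotypes_tsv(path: str) -> GenotypeMatrix:
    chroms = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#chrom"):
            chroms = np.array(first.rstrip("\n").split("\t")[1:])
            df = pd.read_csv(fh, sep="\t", index_col=0, na_values=["NA"])
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0, na_values=["NA"])
    if chroms is None:
        chroms = np.array(["1"] * df.shape[1])
    return GenotypeMatrix(
        values=df.to_numpy(dtype=float),
        individual_ids=np.array(df.index, dtype=str),
        snp_ids=np.array(df.columns, dtype=str),
        chromosomes=chroms,
    )


def write_plink(genotypes: GenotypeMatrix, prefix: str) -> None:
    """Write ``prefix.ped`` and ``prefix.map``; alleles coded A (first) / B (second)."""
    n, m = genotypes.values.shape
    with open(prefix + ".map", "w") as fh:
        for j in range(m):
            # chrom, snp id, genetic distance, bp position (1-based index)
            fh.write(f"{genotypes.chromosomes[j]}\t{genotypes.snp_ids[j]}\t0\t{j + 1}\n")
    code = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
    with open(prefix + ".ped", "w") as fh:
        for i in range(n):
            row = genotypes.values[i]
            fields = ["FAM", str(genotypes.individual_ids[i]), "0", "0", "0", "-9"]
            fields += [code[v] if np.isfinite(v) else "0 0" for v in row]
            fh.write("\t".join(fields) + "\n")


def read_plink(prefix: str) -> GenotypeMatrix:
    snp_ids, chroms = [], []
    with open(prefix + ".map") as fh:
        for line in fh:
            parts = line.split()
            chroms.append(parts[0])
            snp_ids.append(parts[1])
    ids, rows = [], []
    decode = {("A", "A"): 0.0, ("A", "B"): 1.0, ("B", "A"): 1.0, ("B", "B"): 2.0}
    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            ids.append(parts[1])
            alleles = parts[6:]
            row = np.empty(len(snp_ids))
            for j in range(len(snp_ids)):
                pair = (alleles[2 * j], alleles[2 * j + 1])
                row[j] = decode.get(pair, np.nan)
            rows.append(row)
    return GenotypeMatrix(
        values=np.array(rows),
        individual_ids=np.array(ids, dtype=str),
        snp_ids=np.array(snp_ids, dtype=str),
        chromosomes=np.array(chroms),
    )


def write_phenotypes(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("id", "sire_id", "herd"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
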