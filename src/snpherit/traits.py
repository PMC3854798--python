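"""Milk fatty-acid trait derivation.

Seventeen fatty acids (FA), measured as weight proportions of total fat
(g/100 g fat), are combined into the standard saturated/unsaturated
groupings and delta-9-desaturase indices:

* SFA  - the ten saturated FAs C6:0 ... C18:0
* UFA  - the seven unsaturated FAs (MUFA + PUFA)
* MUFA - C14:1 cis-9, C16:1 cis-9, C18:1 trans-11, C18:1 cis-9
* PUFA - C18:2 n-6, C18:3 n-3, CLA cis-9,trans-11
* C6toC14 - the even-chain de novo synthesised SFAs C6:0-C14:0
  (C13:0, an odd-chain FA, is deliberately excluded)

Each desaturase index is product / (product + substrate) for a
product-substrate pair, a proxy for delta-9-desaturase activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FATTY_ACIDS",
    "TraitDefinitionSet",
    "derive_traits",
    "summarize_traits",
    "published_mean_composition",
]

FATTY_ACIDS = [
    "C6:0", "C8:0", "C10:0", "C12:0", "C13:0", "C14:0", "C15:0", "C16:0",
    "C17:0", "C18:0", "C14:1c9", "C16:1c9", "C18:1t11", "C18:1c9",
    "C18:2n6", "C18:3n3", "CLAc9t11",
]


@dataclass
class TraitDefinitionSet:
    sfa: tuple = ("C6:0", "C8:0", "C10:0", "C12:0", "C13:0", "C14:0", "C15:0", "C16:0", "C17:0", "C18:0")
    mufa: tuple = ("C14:1c9", "C16:1c9", "C18:1t11", "C18:1c9")
    pufa: tuple = ("C18:2n6", "C18:3n3", "CLAc9t11")
    c6toc14: tuple = ("C6:0", "C8:0", "C10:0", "C12:0", "C14:0")
    # (index name, product, substrate)
    index_pairs: tuple = (
        ("C14index", "C14:1c9", "C14:0"),
        ("C16index", "C16:1c9", "C16:0"),
        ("C18index", "C18:1c9", "C18:0"),
        ("CLAindex", "CLAc9t11", "C18:1t11"),
    )
    groups: dict = field(init=False)

    @property
    def ufa(self) -> tuple:
        return self.mufa + self.pufa

    def __post_init__(self) -> None:
        all_fa = set(self.sfa) | set(self.ufa)
        if all_fa != set(FATTY_ACIDS):
            raise ValueError("SFA and UFA together must cover the 17 measured FAs")
        if set(self.sfa) & set(self.ufa):
            raise ValueError("SFA and UFA must be disjoint")
        if set(self.mufa) & set(self.pufa):
            raise ValueError("MUFA and PUFA must be disjoint")
        if not set(self.c6toc14) <= set(self.sfa):
            raise ValueError("C6toC14 must be a subset of SFA")
        self.groups = {
            "SFA": list(self.sfa),
            "UFA": list(self.ufa),
            "MUFA": list(self.mufa),
            "PUFA": list(self.pufa),
            "C6toC14": list(self.c6toc14),
        }


def derive_traits(table: pd.DataFrame, defs: TraitDefinitionSet | None = None) -> pd.DataFrame:
    """Append FA groups and desaturase indices to a per-cow FA table.

    Group values are per-cow sums of member proportions; indices are
    per-cow product/(product+substrate) ratios, left missing (and logged)
    where product + substrate is zero.
    """
    if defs is None:
        defs = TraitDefinitionSet()
    missing = [fa for fa in FATTY_ACIDS if fa not in table.columns]
    if missing:
        raise KeyError(f"fatty-acid column(s) missing from the table: {missing}")
    out = table.copy()
    for group, members in defs.groups.items():
        out[group] = table[members].sum(axis=1)
    for name, product, substrate in defs.index_pairs:
        denom = table[product] + table[substrate]
        zero = denom == 0
        if zero.any():
            logger.warning("%s undefined for %d cow(s): product+substrate is zero", name, int(zero.sum()))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = np.where(zero, np.nan, table[product] / denom)
    return out


def summarize_traits(pheno: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Per-trait mean, sample SD, CV (%) and median.

    CV is SD/mean * 100; for a zero mean it is reported missing (and
    logged) rather than infinite.
    """
    if columns is None:
        columns = [c for c in pheno.columns if pd.api.types.is_numeric_dtype(pheno[c]) and c != "parity"]
    if len(pheno) < 2:
        raise ValueError("need at least two cows to summarise")
    rows = []
    for col in columns:
        x = pheno[col].dropna()
        mean, sd = x.mean(), x.std(ddof=1)
        if mean == 0.0:
            if sd != 0.0:
                logger.warning("CV undefined for %s: zero mean with nonzero SD", col)
            cv = np.nan if sd != 0.0 else 0.0
        else:
            cv = sd / mean * 100.0
        rows.append({"trait": col, "mean": mean, "SD": sd, "CV": cv, "median": x.median()})
    return pd.DataFrame(rows).set_index("trait")


# Printed per-trait means of the study's composition table: fat in
# g/100 g milk, fatty acids in g/100 g fat.
_PUBLISHED_MEANS = {
    "fat": 3.99,
    "C6:0": 2.69, "C8:0": 1.47, "C10:0": 3.16, "C12:0": 3.57, "C13:0": 0.10,
    "C14:0": 11.29, "C15:0": 1.10, "C16:0": 28.95, "C17:0": 0.53, "C18:0": 10.54,
    "C14:1c9": 0.97, "C16:1c9": 1.50, "C18:1t11": 1.70, "C18:1c9": 19.78,
    "C18:2n6": 1.69, "C18:3n3": 0.49, "CLAc9t11": 0.63,
}


def published_mean_composition() -> pd.Series:
    """The published mean milk-fat composition, as a single 'mean cow'.

    Returns the 17 individual fatty-acid means plus the fat mean; useful
    for exact composition arithmetic (group sums, index ratios).
    """
    return pd.Series(_PUBLISHED_MEANS, dtype=float)
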