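"""End-to-end orchestration: simulate -> QC -> chains -> GRM -> REML -> report.

The report bundle mirrors the layout a genetic-parameter study prints:

* a descriptive table per trait (mean, SD, CV, median) joined with the
  posterior-mean heritability and its posterior SD;
* a square trait-by-trait correlation matrix with the genomic
  correlation above the diagonal and the environmental correlation
  below it;
* a method-comparison table (Bayesian vs REML genomic correlation per
  pair, with raw phenotypic correlations and REML boundary flags) plus
  the two scatter plots.

Every random stage derives a child seed deterministically from the run
seed, and the run log records seeds and dimensions, so a run can be
reproduced from its log alone.
"""

from __future__ import annotations

import itertools
import json
import logging
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .grm import GRM, compute_grm
from .mcmc import MCMCConfig, build_model_frame, run_bivariate_chain, run_univariate_chain
from .qc import QCThresholds, apply_qc, center_genotypes
from .reml import (
    REMLOptions,
    compare_bayes_reml,
    plot_method_comparison,
    plot_phenotypic_vs_genomic,
    reml_bivariate,
    reml_univariate,
)
from .simulate import SimulationConfig, make_study_like_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "phenotypic_correlation"]


@dataclass
class RunConfig:
    output_dir: str = "snpherit_run"
    # either a simulation preset or explicit input paths
    simulate: bool = True
    simulation_seed: int = 1
    genotype_path: str | None = None
    phenotype_path: str | None = None
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    reml_options: REMLOptions = field(default_factory=REMLOptions)
    traits: list[str] | None = None        # default: all trait columns
    pairs: list[tuple[str, str]] | None = None  # default: all pairs
    run_reml: bool = True
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = QCThresholds(**kwargs["thresholds"])
        if "mcmc" in kwargs:
            kwargs["mcmc"] = MCMCConfig(**kwargs["mcmc"])
        if "reml_options" in kwargs:
            kwargs["reml_options"] = REMLOptions(**kwargs["reml_options"])
        if "pairs" in kwargs and kwargs["pairs"] is not None:
            kwargs["pairs"] = [tuple(p) for p in kwargs["pairs"]]
        return cls(**kwargs)


def phenotypic_correlation(
    pheno: pd.DataFrame, pair: tuple[str, str], adjusted: bool = False
) -> float:
    """Pearson correlation of two raw trait columns.

    ``adjusted=True`` correlates the residuals after removing herd and
    parity means instead (the fixed-effect-adjusted variant); the default
    is the raw correlation.
    """
    a = pheno[pair[0]]
    b = pheno[pair[1]]
    ok = a.notna() & b.notna()
    if ok.sum() < 3:
        raise ValueError("need at least three jointly observed individuals")
    x, y = a[ok].to_numpy(float), b[ok].to_numpy(float)
    if adjusted:
        sub = pheno.loc[ok]
        groups = sub["herd"].astype(str) + "/" + sub["parity"].astype(str)
        for arr in (x, y):
            means = pd.Series(arr).groupby(groups.to_numpy()).transform("mean").to_numpy()
            arr -= means
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        logger.warning("phenotypic correlation undefined for %s: constant column", pair)
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _seed_for(base: int, stage: str, index: int = 0) -> int:
    """Deterministic child seed per stage (kept below 2^31)."""
    tag = zlib.crc32(stage.encode()) % 2**31
    ss = np.random.SeedSequence([base, tag, index])
    return int(ss.generate_state(1)[0] % 2**31)


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.output_dir``.

    Returns a dict with the QC report, per-trait posterior summaries, the
    correlation matrix, the REML results and the comparison table. Any
    stage failure is re-raised annotated with the stage name; artifacts
    completed before the failure stay on disk.
    """
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    bundle: dict = {}
    stage = "input"
    try:
        if config.simulate:
            stage = "simulate"
            logger.info("simulate: study-like preset, seed=%d", config.simulation_seed)
            genotypes, pheno, truth = make_study_like_dataset(config.simulation_seed)
            sio.write_genotypes_tsv(genotypes, os.path.join(out, "genotypes.tsv"))
            sio.write_phenotypes(pheno, os.path.join(out, "phenotypes.tsv"))
            truth.to_json(os.path.join(out, "simulation_truth.json"))
            bundle["truth"] = truth
        else:
            genotypes = sio.read_genotypes_tsv(config.genotype_path)
            pheno = sio.read_phenotypes(config.phenotype_path)

        stage = "qc"
        genotypes, qc_report = apply_qc(genotypes, config.thresholds)
        with open(os.path.join(out, "qc_report.json"), "w") as fh:
            json.dump(qc_report.to_dict(), fh, indent=1)
        bundle["qc_report"] = qc_report
        keep = set(genotypes.individual_ids)
        pheno = pheno[pheno["id"].isin(keep)].reset_index(drop=True)

        stage = "center"
        design = center_genotypes(genotypes)

        traits = config.traits
        if traits is None:
            reserved = {"id", "sire_id", "herd", "parity"}
            traits = [c for c in pheno.columns if c not in reserved]
        pairs = config.pairs or list(itertools.combinations(traits, 2))

        stage = "univariate chains"
        summaries = {}
        for k, trait in enumerate(traits):
            frame = build_model_frame(pheno, trait, design)
            cfg_t = MCMCConfig(
                n_iterations=config.mcmc.n_iterations,
                burn_in=config.mcmc.burn_in,
                thin=config.mcmc.thin,
                seed=_seed_for(config.mcmc.seed, "univariate", k),
                sampler=config.mcmc.sampler,
                variance_upper_bound=config.mcmc.variance_upper_bound,
            )
            chain, summary = run_univariate_chain(frame, cfg_t)
            chain.to_tsv(os.path.join(out, f"chain_{trait}.tsv"))
            summaries[trait] = summary
        bundle["univariate"] = summaries

        stage = "bivariate chains"
        bivariate = {}
        for k, pair in enumerate(pairs):
            frame = build_model_frame(pheno, list(pair), design)
            cfg_p = MCMCConfig(
                n_iterations=config.mcmc.n_iterations,
                burn_in=config.mcmc.burn_in,
                thin=config.mcmc.thin,
                seed=_seed_for(config.mcmc.seed, "bivariate", k),
                sampler=config.mcmc.sampler,
                variance_upper_bound=config.mcmc.variance_upper_bound,
            )
            chain, post = run_bivariate_chain(frame, cfg_p)
            chain.to_tsv(os.path.join(out, f"chain_{pair[0]}_{pair[1]}.tsv"))
            bivariate[pair] = post
        bundle["bivariate"] = bivariate

        stage = "summary table"
        desc = []
        for t in traits:
            x = pheno[t].dropna()
            s = summaries[t]
            desc.append(
                {
                    "trait": t,
                    "mean": x.mean(),
                    "SD": x.std(ddof=1),
                    "CV": x.std(ddof=1) / x.mean() * 100.0 if x.mean() != 0 else np.nan,
                    "median": x.median(),
                    "h2": s.h2_mean,
                    "psd": s.h2_psd,
                }
            )
        summary_table = pd.DataFrame(desc).set_index("trait")
        summary_table.to_csv(os.path.join(out, "trait_summary.tsv"), sep="\t")
        bundle["summary_table"] = summary_table

        # correlation matrix: genomic above the diagonal, environmental below
        corr = pd.DataFrame(np.nan, index=traits, columns=traits)
        for (t1, t2), post in bivariate.items():
            i, j = traits.index(t1), traits.index(t2)
            a, b = min(i, j), max(i, j)
            corr.iloc[a, b] = post.genomic_correlation_mean
            corr.iloc[b, a] = post.environmental_correlation_mean
        corr.to_csv(os.path.join(out, "correlation_matrix.tsv"), sep="\t")
        bundle["correlation_matrix"] = corr

        if config.run_reml:
            stage = "grm"
            G = compute_grm(genotypes)
            G.to_tsv(os.path.join(out, "grm.tsv"))

            stage = "reml"
            id_order = pheno.set_index("id").loc[list(genotypes.individual_ids)].reset_index()
            reml_uni = {}
            for t in traits:
                ok = id_order[t].notna().to_numpy()
                sub = id_order.loc[ok]
                Gsub = GRM(
                    G.values[np.ix_(ok, ok)], G.scaling_denominator, sub["id"].to_numpy(str)
                )
                reml_uni[t] = reml_univariate(
                    sub[t].to_numpy(float), sub["herd"], sub["parity"], Gsub,
                    config.reml_options,
                )
            reml_pairs = []
            pheno_corrs = []
            for pair in pairs:
                ok = id_order[list(pair)].notna().all(axis=1).to_numpy()
                sub = id_order.loc[ok]
                Gsub = GRM(
                    G.values[np.ix_(ok, ok)], G.scaling_denominator, sub["id"].to_numpy(str)
                )
                reml_pairs.append(
                    reml_bivariate(
                        sub[pair[0]].to_numpy(float), sub[pair[1]].to_numpy(float),
                        sub["herd"], sub["parity"], Gsub, config.reml_options,
                    )
                )
                pheno_corrs.append(phenotypic_correlation(pheno, pair))
            bundle["reml_univariate"] = reml_uni
            bundle["reml_bivariate"] = reml_pairs
            with open(os.path.join(out, "reml_results.json"), "w") as fh:
                json.dump(
                    {
                        "univariate": {t: r.to_dict() for t, r in reml_uni.items()},
                        "bivariate": [r.to_dict() for r in reml_pairs],
                    },
                    fh,
                    indent=1,
                )

            stage = "compare"
            table = compare_bayes_reml(
                [bivariate[p] for p in pairs], reml_pairs, pairs, pheno_corrs
            )
            table.to_csv(os.path.join(out, "method_comparison.tsv"), sep="\t", index=False)
            bundle["comparison"] = table
            if config.make_plots:
                plot_method_comparison(table, os.path.join(out, "bayes_vs_reml.png"))
                plot_phenotypic_vs_genomic(table, os.path.join(out, "phenotypic_vs_genomic.png"))
    except Exception as err:
        raise RuntimeError(f"pipeline failed during stage '{stage}': {err}") from err
    return bundle
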