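"""Configuration-driven orchestration of the full analysis.

``run_grid`` evaluates the Cartesian product of clumping windows, LD
cut-offs, and p-value ceilings on the training cohort (the reference design
is 3 windows x 4 r2 x 4 ceilings = 48 combinations) and selects the
combination maximizing the PRS-specific Nagelkerke R2. ``run_full`` executes
the whole protocol: split, grid search on training, refit of the selected
parameters on validation (re-scanning only the fine inclusion threshold),
performance tables, covariate scenarios, leave-one-out variant ranking with
carrier-ancestry profiles, and multi-split stability.

All randomness flows from one master seed through fixed, named offsets
(synthetic +0, phenotype +2, base GWAS +3, split +101, permutations +202,
stability splits +303+i), so each stage is independently reproducible.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import io as aio
from .ancestry import AncestryIndex, carrier_ancestry, covariates_from_proportions, global_proportions
from .contribution import loo_delta_auc, top_k_report
from .evaluation import (
    auc,
    confusion_at,
    multi_split_stability,
    predictive_values,
    split_cohort,
)
from .harmonize import clump, harmonize
from .scoring import (
    DEFAULT_PREVALENCE,
    empirical_p,
    threshold_scan,
)
from .scenarios import run_scenarios, scenarios_table
from .simulate import default_cohort
from .types import HaplotypeCohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_grid", "run_full", "cohort_covariates"]

DEFAULT_WINDOWS_KB = (100.0, 250.0, 500.0)
DEFAULT_R2 = (0.1, 0.2, 0.5, 0.8)
DEFAULT_CEILINGS = (1e-3, 1e-5, 1e-6, 5e-8)
DEFAULT_PERCENTILES = (0.05, 0.10, 0.20)


@dataclass
class RunConfig:
    """Inputs, parameter grid, and output location for one full run.

    Either the ``synthetic`` block or the explicit input paths must be
    present. ``n_perm`` defaults to the reference 10,000; scaled-down runs
    record the value they used in the run log.
    """

    seed: int = 1
    synthetic: dict | None = field(
        default_factory=lambda: {"n_samples": 1398, "n_variants": 1200,
                                 "base_n": 40000}
    )
    sumstats_path: str | None = None
    genotypes_path: str | None = None
    segments_path: str | None = None
    covariates_path: str | None = None
    phenotype_path: str | None = None
    windows_kb: tuple = DEFAULT_WINDOWS_KB
    r2_values: tuple = DEFAULT_R2
    ceilings: tuple = DEFAULT_CEILINGS
    n_perm: int = 10_000
    split_proportion: float = 0.7
    prevalence: float = DEFAULT_PREVALENCE
    percentiles: tuple = DEFAULT_PERCENTILES
    drop_ancestry: str = "MAL"
    stability_splits: int = 20
    loo_top_k: int = 10
    out_dir: str | None = None

    def __post_init__(self):
        paths = (self.sumstats_path, self.genotypes_path)
        if self.synthetic is None and any(p is None for p in paths):
            raise ValueError("either synthetic block or input paths required")
        if not self.windows_kb or not self.r2_values or not self.ceilings:
            raise ValueError("empty parameter grid")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("windows_kb", "r2_values", "ceilings", "percentiles"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def cohort_covariates(cohort: HaplotypeCohort, drop_ancestry: str = "MAL"):
    """AGE/SEX plus retained ancestry-proportion columns, sample-aligned.

    Returns (covariate frame, retained ancestry column names).
    """
    props = global_proportions(cohort.segments, cohort.ancestry_labels)
    props = props.loc[cohort.samples]
    anc = covariates_from_proportions(props, drop_label=drop_ancestry)
    cov = cohort.covariate_frame().join(anc)
    return cov, list(anc.columns)


def run_grid(
    harmonized,
    dosages,
    phenotype,
    covariates,
    windows_kb=DEFAULT_WINDOWS_KB,
    r2_values=DEFAULT_R2,
    ceilings=DEFAULT_CEILINGS,
    prevalence: float = DEFAULT_PREVALENCE,
):
    """Evaluate every window x r2 x ceiling combination on one cohort.

    Returns (per-combination table, best row dict, best ScanResult). The
    best combination maximizes r2_prs; ties break toward the smaller
    ceiling, then window, then r2.
    """
    if not windows_kb or not r2_values or not ceilings:
        raise ValueError("empty parameter grid")
    rows = []
    scans = {}
    for w, r2 in product(windows_kb, r2_values):
        cres = clump(harmonized, dosages, window_kb=w, r2_max=r2)
        for c in ceilings:
            scan = threshold_scan(
                harmonized, cres, dosages, phenotype, covariates,
                ceiling=c, prevalence=prevalence,
            )
            key = (w, r2, c)
            scans[key] = scan
            best = scan.best
            rows.append(
                {
                    "window_kb": w,
                    "r2_max": r2,
                    "ceiling": c,
                    "n_index": len(cres.index_variants),
                    "best_threshold": None if best is None else best.best_threshold,
                    "n_snps": None if best is None else best.n_snps,
                    "r2_prs": None if best is None else best.r2_prs,
                    "r2_full": None if best is None else best.r2_full,
                    "r2_null": None if best is None else best.r2_null,
                    "p": None if best is None else best.p_model,
                }
            )
    table = pd.DataFrame(rows)
    usable = table.dropna(subset=["r2_prs"])
    if usable.empty:
        raise ValueError("no grid combination produced a usable model")
    best_row = usable.sort_values(
        ["r2_prs", "ceiling", "window_kb", "r2_max"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).iloc[0]
    key = (best_row["window_kb"], best_row["r2_max"], best_row["ceiling"])
    return table, best_row.to_dict(), scans[key]


def _performance_block(scan, phenotype, covariates, sample_ids, percentiles,
                       prevalence):
    """Table-1-style metrics for one cohort's selected model."""
    from .scoring import _covariate_matrix, _logit_fit

    best = scan.best
    y = np.asarray(phenotype, dtype=int)
    prs = scan.score_matrix[:, scan.best_index]
    C, _ = _covariate_matrix(covariates)
    X = np.column_stack([np.ones(len(y)), prs] + ([C] if C.size else []))
    coefs, _, _ = _logit_fit(X, y.astype(float))
    probs = expit(X @ coefs)
    roc = auc(probs, y)
    conf = confusion_at(probs, y, 0.5)
    pvs = [
        predictive_values(prs, y, pct, prevalence, sample_ids)
        for pct in percentiles
    ]
    return {
        "best_threshold": best.best_threshold,
        "n_snps": best.n_snps,
        "prs_r2": best.r2_prs,
        "prs_r2_adjusted": best.r2_prs_adjusted,
        "full_r2": best.r2_full,
        "null_r2": best.r2_null,
        "coefficient": best.coef_prs,
        "se": best.se_prs,
        "p": best.p_model,
        "empirical_p": best.empirical_p,
        "auc": roc.auc,
        "auc_ci_low": roc.ci_low,
        "auc_ci_high": roc.ci_high,
        "accuracy": conf.accuracy,
        "balanced_accuracy": conf.balanced_accuracy,
        "sensitivity": conf.sensitivity,
        "specificity": conf.specificity,
        "predictive_values": [asdict(p) for p in pvs],
    }


def _load_inputs(config: RunConfig):
    """Materialize (cohort, sumstats) from the synthetic block or files."""
    if config.synthetic is not None:
        syn = dict(config.synthetic)
        cohort, sumstats = default_cohort(
            seed=config.seed,
            n_samples=int(syn.get("n_samples", 1398)),
            n_variants=int(syn.get("n_variants", 1200)),
            base_n=int(syn.get("base_n", 40000)),
        )
        return cohort, sumstats
    sumstats = aio.read_sumstats(config.sumstats_path)
    geno = aio.read_genotypes(config.genotypes_path)
    if geno.haplotypes is None:
        raise ValueError("full pipeline requires phased genotypes")
    segments = aio.read_segments(config.segments_path)
    cov = aio.read_covariates(config.covariates_path)
    pheno = aio.read_phenotype(config.phenotype_path)
    cov, pheno = aio.align_samples(geno.samples, cov, pheno)
    labels = tuple(
        sorted({s.ancestry for s in segments})
    )
    chrom_lengths: dict[str, int] = {}
    for s in segments:
        chrom_lengths[s.chrom] = max(chrom_lengths.get(s.chrom, 0), s.end)
    cohort = HaplotypeCohort(
        samples=geno.samples,
        variants=geno.variants,
        alleles=geno.haplotypes,
        age=cov["AGE"].to_numpy(dtype=float),
        sex=cov["SEX"].to_numpy(dtype=float),
        segments=segments,
        ancestry_labels=labels,
        chrom_lengths=chrom_lengths,
        phenotype=pheno.to_numpy(),
    )
    return cohort, sumstats


def run_full(config: RunConfig) -> dict:
    """Execute the full protocol and return the report bundle.

    The bundle carries the grid table, training/validation performance
    blocks, the covariate-scenario table, the LOO top-k table with carrier
    profiles, the multi-split stability summary, and a run log. When
    ``config.out_dir`` is set, each table is also written as TSV/JSON.
    """
    cohort, sumstats = _load_inputs(config)
    if cohort.phenotype is None:
        raise ValueError("cohort has no phenotype")
    covariates, anc_cols = cohort_covariates(cohort, config.drop_ancestry)

    plan = split_cohort(cohort.samples, config.split_proportion,
                        seed=config.seed + 101)
    train = cohort.subset(list(plan.train_ids))
    valid = cohort.subset(list(plan.valid_ids))
    cov_train = covariates.loc[list(plan.train_ids)]
    cov_valid = covariates.loc[list(plan.valid_ids)]

    harmonized_train = harmonize(sumstats, train.variants)
    d_train = train.dosages
    d_valid = valid.dosages

    grid_table, best_combo, best_scan = run_grid(
        harmonized_train, d_train, train.phenotype, cov_train,
        config.windows_kb, config.r2_values, config.ceilings,
        config.prevalence,
    )
    if config.n_perm:
        empirical_p(best_scan, train.phenotype, cov_train,
                    n_perm=config.n_perm, seed=config.seed + 202)

    # validation: training-selected window/r2/ceiling, fine threshold re-scanned
    cres_valid = clump(
        harmonized_train, d_valid,
        window_kb=best_combo["window_kb"], r2_max=best_combo["r2_max"],
    )
    scan_valid = threshold_scan(
        harmonized_train, cres_valid, d_valid, valid.phenotype, cov_valid,
        ceiling=best_combo["ceiling"], prevalence=config.prevalence,
    )
    if scan_valid.best is None:
        raise ValueError("validation stage produced no usable model")
    if config.n_perm:
        empirical_p(scan_valid, valid.phenotype, cov_valid,
                    n_perm=config.n_perm, seed=config.seed + 203)

    perf = {
        "training": _performance_block(
            best_scan, train.phenotype, cov_train, train.samples,
            config.percentiles, config.prevalence,
        ),
        "validation": _performance_block(
            scan_valid, valid.phenotype, cov_valid, valid.samples,
            config.percentiles, config.prevalence,
        ),
    }

    scen = run_scenarios(
        harmonized_train,
        clump(harmonized_train, d_train,
              best_combo["window_kb"], best_combo["r2_max"]),
        d_train, train.phenotype, covariates.loc[list(plan.train_ids)],
        anc_cols, ceiling=best_combo["ceiling"], n_perm=0,
        prevalence=config.prevalence,
    )
    scen_table = scenarios_table(scen)

    # leave-one-out ranking on the training cohort's final model
    final_snps = best_scan.included_sets[best_scan.best_index]
    loo_table, cumulative = None, None
    if len(final_snps) >= 2:
        contribs = loo_delta_auc(final_snps, d_train, train.phenotype, cov_train)
        idx = AncestryIndex(train.segments)
        for c in contribs:
            c.carrier_profile = carrier_ancestry(c.variant, train, idx)
        k = min(config.loo_top_k, len(contribs))
        loo_table, cumulative = top_k_report(contribs, k=k)

    def _stability_run(sp):
        tr = cohort.subset(list(sp.train_ids))
        va = cohort.subset(list(sp.valid_ids))
        ctr = covariates.loc[list(sp.train_ids)]
        cva = covariates.loc[list(sp.valid_ids)]
        h = harmonize(sumstats, tr.variants)
        # refit on validation with the training-selected parameters
        cres_v = clump(h, va.dosages, best_combo["window_kb"], best_combo["r2_max"])
        scan_v = threshold_scan(h, cres_v, va.dosages, va.phenotype, cva,
                                ceiling=best_combo["ceiling"],
                                prevalence=config.prevalence)
        if scan_v.best is None:
            raise ValueError("no usable validation model for this split")
        return _performance_block(
            scan_v, va.phenotype, cva, va.samples, config.percentiles,
            config.prevalence,
        )["auc"]

    stability_table, stab_mean, stab_sd = multi_split_stability(
        _stability_run,
        cohort.samples,
        k=config.stability_splits,
        seeds=[config.seed + 303 + i for i in range(config.stability_splits)],
        proportion=config.split_proportion,
    )

    run_log = {
        "seed": config.seed,
        "n_perm": config.n_perm,
        "n_samples": cohort.n_samples,
        "n_variants": cohort.n_variants,
        "split": {"train": len(plan.train_ids), "valid": len(plan.valid_ids)},
        "best_combo": {k: float(v) for k, v in best_combo.items()
                       if isinstance(v, (int, float))},
        "dropped_ancestry": config.drop_ancestry,
    }
    bundle = {
        "grid": grid_table,
        "best_combo": best_combo,
        "performance": perf,
        "scenarios": scen_table,
        "loo": loo_table,
        "loo_cumulative": cumulative,
        "stability": stability_table,
        "stability_mean": stab_mean,
        "stability_sd": stab_sd,
        "run_log": run_log,
        "split_plan": plan,
    }
    if config.out_dir:
        _write_bundle(bundle, config.out_dir)
    return bundle


def _write_bundle(bundle: dict, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    bundle["grid"].to_csv(os.path.join(out_dir, "grid_results.tsv"),
                          sep="\t", index=False)
    bundle["scenarios"].to_csv(os.path.join(out_dir, "covariate_scenarios.tsv"),
                               sep="\t", index=False)
    if bundle["loo"] is not None:
        bundle["loo"].to_csv(os.path.join(out_dir, "loo_top_variants.tsv"),
                             sep="\t", index=False)
    bundle["stability"].to_csv(os.path.join(out_dir, "split_stability.tsv"),
                               sep="\t", index=False)
    with open(os.path.join(out_dir, "performance.json"), "w",
              encoding="utf-8") as fh:
        json.dump(bundle["performance"], fh, indent=2, default=float)
    with open(os.path.join(out_dir, "run.log"), "w", encoding="utf-8") as fh:
        json.dump(bundle["run_log"], fh, indent=2, default=float)
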