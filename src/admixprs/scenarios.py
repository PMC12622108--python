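"""The seven covariate-inclusion scenarios.

All non-empty subsets of {AGE, SEX, ANC} — where ANC is an atomic block of
the retained ancestry-proportion columns — are evaluated: the threshold scan
is re-run under each covariate set (the best SNP count differs per
scenario), the variance decomposition recorded, and the covariates-only
versus covariates+PRS AUCs compared with the DeLong test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit

from .evaluation import RocResult, auc, delong_test
from .harmonize import ClumpResult, HarmonizedVariant
from .scoring import (
    DEFAULT_PREVALENCE,
    ModelFit,
    SeparationError,
    _covariate_matrix,
    _logit_fit,
    empirical_p,
    threshold_scan,
)

logger = logging.getLogger(__name__)

__all__ = ["ScenarioResult", "enumerate_scenarios", "run_scenarios",
           "scenarios_table"]

_GROUPS = ("AGE", "SEX", "ANC")


@dataclass
class ScenarioResult:
    covariate_set: tuple[str, ...]
    model_fit: ModelFit | None
    auc_covariates_only: RocResult | None
    auc_full: RocResult | None
    delong_p: float | None
    error: str = ""


def enumerate_scenarios() -> list[tuple[str, ...]]:
    """All 7 non-empty subsets of {AGE, SEX, ANC}, singletons first."""
    out: list[tuple[str, ...]] = []
    for r in (1, 2, 3):
        out.extend(combinations(_GROUPS, r))
    return out


def _design_columns(
    scenario: tuple[str, ...], covariates: pd.DataFrame, ancestry_cols: list[str]
) -> pd.DataFrame:
    cols: list[str] = []
    if "AGE" in scenario:
        cols.append("AGE")
    if "SEX" in scenario:
        cols.append("SEX")
    if "ANC" in scenario:
        cols.extend(ancestry_cols)
    return covariates[cols]


def _fitted_probs(phenotype, prs, covariates) -> np.ndarray:
    y = np.asarray(phenotype, dtype=float)
    C, _ = _covariate_matrix(covariates)
    parts = [np.ones(len(y))]
    if prs is not None:
        parts.append(np.asarray(prs, dtype=float))
    if C.size:
        parts.append(C)
    X = np.column_stack(parts)
    coefs, _, _ = _logit_fit(X, y)
    return expit(X @ coefs)


def run_scenarios(
    harmonized: list[HarmonizedVariant],
    clump_result: ClumpResult,
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
    ancestry_cols: list[str],
    ceiling: float = 1e-3,
    n_perm: int = 0,
    seed: int = 0,
    prevalence: float = DEFAULT_PREVALENCE,
) -> list[ScenarioResult]:
    """Variance decomposition and with/without-PRS AUC comparison per
    covariate scenario.

    ``covariates`` must carry AGE, SEX and the retained ancestry columns.
    A rank-deficient scenario is reported with its error; the others
    continue. ``n_perm = 0`` skips permutation p-values.
    """
    results: list[ScenarioResult] = []
    y = np.asarray(phenotype, dtype=int)
    for scenario in enumerate_scenarios():
        cov = _design_columns(scenario, covariates, ancestry_cols)
        try:
            scan = threshold_scan(
                harmonized, clump_result, dosages, phenotype, cov,
                ceiling=ceiling, prevalence=prevalence,
            )
            if scan.best is None:
                raise ValueError("no threshold produced a fit")
            if n_perm:
                empirical_p(scan, phenotype, cov, n_perm=n_perm, seed=seed)
            prs = scan.score_matrix[:, scan.best_index]
            p_cov = _fitted_probs(phenotype, None, cov)
            p_full = _fitted_probs(phenotype, prs, cov)
            roc_cov = auc(p_cov, y)
            roc_full = auc(p_full, y)
            _, dl_p = delong_test(p_full, p_cov, y)
            results.append(
                ScenarioResult(scenario, scan.best, roc_cov, roc_full, dl_p)
            )
        except (ValueError, SeparationError, np.linalg.LinAlgError) as e:
            logger.warning("scenario %s failed: %s", scenario, e)
            results.append(ScenarioResult(scenario, None, None, None, None, str(e)))
    return results


def scenarios_table(results: list[ScenarioResult]) -> pd.DataFrame:
    """Variance-decomposition rows (one per covariate scenario)."""
    rows = []
    for r in results:
        f = r.model_fit
        rows.append(
            {
                "covariates": "+".join(r.covariate_set),
                "prs_r2": None if f is None else f.r2_prs,
                "prs_r2_adjusted": None if f is None else f.r2_prs_adjusted,
                "full_r2": None if f is None else f.r2_full,
                "null_r2": None if f is None else f.r2_null,
                "n_snps": None if f is None else f.n_snps,
                "empirical_p": None if f is None else f.empirical_p,
                "auc_covariates_only": None
                if r.auc_covariates_only is None
                else r.auc_covariates_only.auc,
                "auc_full": None if r.auc_full is None else r.auc_full.auc,
                "delong_p": r.delong_p,
                "error": r.error,
            }
        )
    return pd.DataFrame(rows)
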