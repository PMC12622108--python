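"""Leave-one-SNP-out variant ranking.

Each variant in the final model is removed in turn — betas and the remaining
SNP set frozen, no re-clumping or re-thresholding — the score rebuilt, the
full logistic model refit, and the AUC recomputed. Variants are ranked by the
resulting change in AUC (most negative = largest contribution).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .ancestry import CarrierAncestryProfile
from .evaluation import auc
from .harmonize import HarmonizedVariant
from .scoring import SeparationError, _covariate_matrix, _logit_fit, score
from .types import VariantRecord

__all__ = ["VariantContribution", "loo_delta_auc", "top_k_report"]


@dataclass
class VariantContribution:
    variant: VariantRecord
    auc_without: float
    delta_auc: float  # auc_without - auc_full; negative = contributes
    rank: int  # 1 = largest decrease
    carrier_profile: CarrierAncestryProfile | None = None
    annotation: str = ""


def _model_auc(phenotype, prs, covariates) -> float:
    y = np.asarray(phenotype, dtype=float)
    C, _ = _covariate_matrix(covariates)
    X = np.column_stack([np.ones(len(y)), prs] + ([C] if C.size else []))
    coefs, _, _ = _logit_fit(X, y)
    return auc(expit(X @ coefs), y.astype(int)).auc


def loo_delta_auc(
    final_model_snps: list[HarmonizedVariant],
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates=None,
) -> list[VariantContribution]:
    """Rank the final model's SNPs by leave-one-out AUC change.

    The covariate model is refit per removal; the AUC is computed on the
    cohort whose dosages/phenotype are supplied (the training cohort in the
    reference protocol). Requires at least two SNPs.
    """
    if len(final_model_snps) < 2:
        raise ValueError("LOO is undefined for a single-SNP model")
    full = score(dosages, final_model_snps)
    auc_full = _model_auc(phenotype, full.scores, covariates)
    out: list[VariantContribution] = []
    for j, h in enumerate(final_model_snps):
        rest = final_model_snps[:j] + final_model_snps[j + 1:]
        if h.beta_aligned == 0.0:
            # score unchanged; no refit needed
            out.append(VariantContribution(h.variant, auc_full, 0.0, 0))
            continue
        prof = score(dosages, rest)
        try:
            a = _model_auc(phenotype, prof.scores, covariates)
        except (SeparationError, np.linalg.LinAlgError):
            a = np.nan
        out.append(VariantContribution(h.variant, a, a - auc_full, 0))
    out.sort(
        key=lambda c: (np.inf if np.isnan(c.delta_auc) else c.delta_auc, c.variant.id)
    )
    for r, c in enumerate(out, start=1):
        c.rank = r
    return out


def top_k_report(
    contributions: list[VariantContribution],
    k: int = 10,
    auc_full: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Top-k table plus the cumulative difference between the rank-1 and
    rank-k AUC changes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(contributions):
        raise ValueError("k exceeds the number of ranked variants")
    ranked = sorted(contributions, key=lambda c: c.rank)[:k]
    rows = []
    for c in ranked:
        row = {
            "SNP": c.variant.id,
            "rank": c.rank,
            "AUC_without": c.auc_without,
            "annotation": c.annotation,
            "delta_AUC": c.delta_auc,
        }
        if c.carrier_profile is not None:
            row.update(
                {lab: c.carrier_profile.percentages[lab]
                 for lab in c.carrier_profile.percentages}
            )
        rows.append(row)
    cumulative = ranked[0].delta_auc - ranked[-1].delta_auc
    return pd.DataFrame(rows), float(cumulative)
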