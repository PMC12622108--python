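"""Classification performance: ROC/AUC, DeLong tests, confusion metrics,
prevalence-anchored predictive values, and the train/validation protocol.

The AUC is the rank-based (Mann-Whitney) estimator with ties counted one
half; its variance and the paired comparison of two correlated ROC curves
follow DeLong's placement-value construction. Predictive values anchor the
cohort's sensitivity/specificity at a top-percentile PRS flag to an external
population prevalence via Bayes' rule — the cohort case fraction never enters
PPV/NPV directly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "RocResult",
    "ConfusionMetrics",
    "PredictiveValues",
    "SplitPlan",
    "auc",
    "delong_test",
    "confusion_at",
    "predictive_values",
    "split_cohort",
    "multi_split_stability",
]


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float
    threshold: float


@dataclass(frozen=True)
class PredictiveValues:
    percentile: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    prevalence: float
    n_flagged: int


@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple[str, ...]
    valid_ids: tuple[str, ...]
    proportion: float
    seed: int


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values. Returns (V10 per case, V01 per control)."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = len(x), len(y)
    allr = rankdata(np.concatenate([x, y]))
    rx = rankdata(x)
    ry = rankdata(y)
    v10 = (allr[:m] - rx) / n
    v01 = 1.0 - (allr[m:] - ry) / m
    return v10, v01


def _check_two_classes(labels: np.ndarray):
    labels = np.asarray(labels).astype(int)
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("both classes must be present")
    return labels


def auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Mann-Whitney AUC with a DeLong-variance 95% normal CI (clipped to
    [0, 1])."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    v10, v01 = _placements(scores, labels)
    m, n = len(v10), len(v01)
    a = float(v10.mean())
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) + (
        v01.var(ddof=1) / n if n > 1 else 0.0
    )
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return RocResult(
        auc=a,
        ci_low=float(max(a - half, 0.0)),
        ci_high=float(min(a + half, 1.0)),
        n_cases=m,
        n_controls=n,
    )


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Paired DeLong test for two correlated ROC curves on the same samples.

    Returns (z, two-sided p). A zero-variance difference returns p = 1 with a
    warning (by convention the self-comparison case).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("score vectors must be the same length")
    labels = _check_two_classes(labels)
    va10, va01 = _placements(scores_a, labels)
    vb10, vb01 = _placements(scores_b, labels)
    m, n = len(va10), len(va01)
    auc_a, auc_b = va10.mean(), vb10.mean()
    var = 0.0
    if m > 1:
        s10 = np.cov(np.stack([va10, vb10]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2.0 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.stack([va01, vb01]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2.0 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0.0 or not np.isfinite(var):
        warnings.warn("zero variance of the AUC difference; returning p = 1")
        return 0.0, 1.0
    z = float(diff / np.sqrt(var))
    p = float(2.0 * norm.sf(abs(z)))
    return z, p


def confusion_at(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionMetrics:
    """2x2-derived metrics at a fixed probability cut-off (predict case iff
    probability > threshold)."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    labels = _check_two_classes(labels)
    pred = p > threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return ConfusionMetrics(
        sensitivity=sens,
        specificity=spec,
        accuracy=(tp + tn) / len(labels),
        balanced_accuracy=(sens + spec) / 2.0,
        threshold=threshold,
    )


def predictive_values(
    prs_scores: np.ndarray,
    labels: np.ndarray,
    percentile: float,
    prevalence: float,
    sample_ids: list[str] | None = None,
) -> PredictiveValues:
    """PPV/NPV from a top-percentile PRS flag under an external prevalence.

    The top ``percentile`` fraction of scores is flagged (ties broken by
    strict score order then sample ID, so the flagged count is exact);
    cohort sensitivity/specificity at that flag feed Bayes' rule with the
    population prevalence K:
    ``PPV = s.K / (s.K + (1-sp)(1-K))``,
    ``NPV = sp(1-K) / (sp(1-K) + (1-s)K)``.
    """
    if not (0.0 < percentile < 1.0):
        raise ValueError("percentile must lie in (0, 1)")
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    s = np.asarray(prs_scores, dtype=float)
    labels = _check_two_classes(labels)
    n = len(s)
    n_flag = int(np.floor(percentile * n + 0.5))
    if n_flag < 1:
        raise ValueError("empty flagged set at this percentile")
    ids = np.array(sample_ids if sample_ids is not None else [str(i) for i in range(n)])
    order = np.lexsort((ids, -s))  # descending score, ID tie-break
    flagged = np.zeros(n, dtype=bool)
    flagged[order[:n_flag]] = True
    cases = labels == 1
    sens = float(np.sum(flagged & cases) / cases.sum())
    spec = float(np.sum(~flagged & ~cases) / (~cases).sum())
    K = prevalence
    denom_p = sens * K + (1.0 - spec) * (1.0 - K)
    ppv = sens * K / denom_p if denom_p > 0 else 0.0
    denom_n = spec * (1.0 - K) + (1.0 - sens) * K
    npv = spec * (1.0 - K) / denom_n if denom_n > 0 else 0.0
    return PredictiveValues(
        percentile=percentile,
        sensitivity=sens,
        specificity=spec,
        ppv=float(ppv),
        npv=float(npv),
        prevalence=prevalence,
        n_flagged=n_flag,
    )


def split_cohort(
    sample_ids: list[str], proportion: float = 0.7, seed: int = 0
) -> SplitPlan:
    """Uniform random train/validation split without replacement.

    The training size is round-half-up of ``proportion * n`` (0.7 x 1398 =
    978.6 -> 979); the split is unstratified. Both sides must be non-empty.
    """
    if not (0.0 < proportion < 1.0):
        raise ValueError("proportion must lie in (0, 1)")
    ids = list(sample_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(np.floor(proportion * n + 0.5))
    if n_train < 1 or n_train >= n:
        raise ValueError("split leaves an empty cohort")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = tuple(ids[i] for i in perm[:n_train])
    valid = tuple(ids[i] for i in perm[n_train:])
    return SplitPlan(train, valid, proportion, seed)


def multi_split_stability(
    run_split,
    sample_ids: list[str],
    k: int = 20,
    seeds: list[int] | None = None,
    proportion: float = 0.7,
) -> tuple[pd.DataFrame, float, float]:
    """Validation-AUC distribution across k random splits.

    ``run_split`` maps a SplitPlan to a validation AUC; splits whose
    pipeline fails a precondition (e.g. a single-class validation set) are
    reported in the table with the error and excluded from the mean/SD.
    Returns (per-split table, mean AUC, SD).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if seeds is None:
        seeds = list(range(k))
    if len(seeds) != k:
        raise ValueError("seeds must have length k")
    rows = []
    for s in seeds:
        plan = split_cohort(sample_ids, proportion, s)
        try:
            a = float(run_split(plan))
            rows.append({"seed": s, "auc": a, "error": ""})
        except (ValueError, RuntimeError) as e:
            rows.append({"seed": s, "auc": np.nan, "error": str(e)})
    df = pd.DataFrame(rows)
    ok = df["auc"].dropna()
    mean = float(ok.mean()) if len(ok) else np.nan
    sd = float(ok.std(ddof=1)) if len(ok) > 1 else 0.0
    return df, mean, sd
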