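"""PRS scoring, logistic variance decomposition, threshold scan, permutations.

The per-sample score is the classic weighted allele count,
``PRS_i = sum_j beta_j . G_ij`` over the variants surviving clumping and a
p-value ceiling. Model evaluation is a maximum-likelihood logistic regression
of case status on PRS plus covariates (full model) versus covariates alone
(null model); variance explained is Nagelkerke's pseudo-R-squared, decomposed
as ``R2_prs = R2_full - R2_null``, with an optional liability-scale
adjustment for case-control ascertainment (Lee et al. 2012 transformation).

Logistic fits use an in-package Newton solver (log-likelihood tolerance
1e-8, at most 100 iterations, step halving); perfect separation is flagged
when any coefficient diverges past |15|. The solver is deliberately small
and allocation-free because the permutation machinery refits the entire
threshold scan for every phenotype permutation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .harmonize import ClumpResult, HarmonizedVariant, mean_impute

logger = logging.getLogger(__name__)

__all__ = [
    "PRSProfile",
    "ModelFit",
    "ScanResult",
    "SeparationError",
    "score",
    "nagelkerke_r2",
    "liability_adjust",
    "fit_case_control",
    "default_threshold_grid",
    "threshold_scan",
    "empirical_p",
    "DEFAULT_PREVALENCE",
]

#: global Parkinson's disease prevalence used for ascertainment adjustment
DEFAULT_PREVALENCE = 1.386e-4

#: fine-grid step between candidate inclusion thresholds
FINE_STEP = 5e-5
GRID_FLOOR = 5e-8


class SeparationError(RuntimeError):
    """Perfect (quasi-)separation: the MLE diverges."""


@dataclass
class PRSProfile:
    """Per-sample weighted dosage sums for one inclusion threshold."""

    scores: np.ndarray
    n_snps: int
    threshold: float | None = None


@dataclass
class ModelFit:
    """One logistic fit with its variance decomposition.

    ``coef_prs``/``se_prs`` are the PRS coefficient and standard error in the
    full model; ``p_model`` its two-sided Wald p. ``empirical_p`` is attached
    after permutation testing.
    """

    loglik_full: float
    loglik_null: float
    n: int
    coef_prs: float
    se_prs: float
    r2_full: float
    r2_null: float
    r2_prs: float
    r2_prs_adjusted: float
    p_model: float
    coefficients: np.ndarray | None = None
    empirical_p: float | None = None
    best_threshold: float | None = None
    n_snps: int | None = None


def score(
    dosages: np.ndarray,
    included: list[HarmonizedVariant],
    threshold: float | None = None,
) -> PRSProfile:
    """Weighted dosage sum over the included harmonized variants.

    Missing dosages are mean-imputed per variant. The included set must be
    non-empty and free of excluded variants.
    """
    if not included:
        raise ValueError("empty included_set")
    if any(h.exclusion_reason is not None for h in included):
        raise ValueError("included_set contains excluded variants")
    cols = np.array([h.target_index for h in included])
    betas = np.array([h.beta_aligned for h in included])
    d = mean_impute(np.asarray(dosages, dtype=float)[:, cols])
    return PRSProfile(scores=d @ betas, n_snps=len(included), threshold=threshold)


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _logit_fit(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float]:
    """Newton/IRLS logistic MLE. Returns (coef, se, loglik).

    Raises SeparationError on diverging coefficients, np.linalg.LinAlgError
    on a singular information matrix (rank-deficient design).
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll = _loglik(X, y, beta)
    for _ in range(max_iter):
        mu = expit(X @ beta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        step = np.linalg.solve(H, grad)
        new_beta = beta + step
        new_ll = _loglik(X, y, new_beta)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll = _loglik(X, y, new_beta)
            halvings += 1
        beta, improved = new_beta, new_ll - ll
        ll = new_ll
        if np.any(np.abs(beta) > 15.0):
            raise SeparationError("perfect separation: coefficient beyond |15|")
        if abs(improved) < tol:
            break
    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    cov = np.linalg.inv(H)
    return beta, np.sqrt(np.diag(cov)), ll


def nagelkerke_r2(loglik_full: float, loglik_null: float, n: int) -> float:
    """Nagelkerke's pseudo-R-squared: Cox-Snell rescaled by its maximum.

    ``1 - exp(2(ll0 - ll1)/n)`` divided by ``1 - exp(2.ll0/n)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_full < loglik_null - 1e-8:
        raise ValueError("loglik_full < loglik_null: models are not nested")
    loglik_full = max(loglik_full, loglik_null)
    cox_snell = 1.0 - np.exp(2.0 * (loglik_null - loglik_full) / n)
    max_cs = 1.0 - np.exp(2.0 * loglik_null / n)
    if max_cs <= 0.0:
        return 0.0
    return float(cox_snell / max_cs)


def liability_adjust(
    r2_observed: float, case_fraction: float, prevalence: float
) -> float:
    """Observed-scale R2 transformed to the liability scale with an
    ascertainment correction (Lee et al. 2012).

    With prevalence K, case fraction P, liability threshold t = Phi^-1(1-K)
    and z = phi(t): ``C = K(1-K)/z^2 . K(1-K)/(P(1-P))`` and
    ``theta = m(P-K)/(1-K) . (m(P-K)/(1-K) - t)`` with ``m = z/K``; the
    adjusted value is ``R2.C / (1 + R2.C.theta)``. When P = K the correction
    reduces to the pure observed-to-liability scale factor K(1-K)/z^2.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    if not (0.0 < case_fraction < 1.0):
        raise ValueError("case_fraction must lie in (0, 1)")
    K, P = prevalence, case_fraction
    t = norm.isf(K)
    z = norm.pdf(t)
    C = (K * (1.0 - K) / z**2) * (K * (1.0 - K) / (P * (1.0 - P)))
    m = z / K
    d = m * (P - K) / (1.0 - K)
    theta = d * (d - t)
    return float(r2_observed * C / (1.0 + r2_observed * C * theta))


def _covariate_matrix(covariates) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((0, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"C{i}" for i in range(arr.shape[1])]


def fit_case_control(
    phenotype: np.ndarray,
    prs: np.ndarray,
    covariates=None,
    prevalence: float = DEFAULT_PREVALENCE,
) -> ModelFit:
    """Logistic fit of case status on PRS + covariates, decomposed against
    the covariates-only null.

    Raises ValueError for constant covariate columns or rank-deficient
    designs and SeparationError on perfect separation. A zero-variance PRS
    column yields ``r2_prs = 0`` and ``p_model = 1`` (the full model equals
    the null).
    """
    y = np.asarray(phenotype, dtype=float)
    prs = np.asarray(prs, dtype=float)
    n = len(y)
    C, names = _covariate_matrix(covariates)
    if C.size:
        const = [names[k] for k in range(C.shape[1]) if np.ptp(C[:, k]) == 0.0]
        if const:
            raise ValueError(f"constant covariate column(s): {const}")
    X_null = np.column_stack([np.ones(n)] + ([C] if C.size else []))
    if np.linalg.matrix_rank(X_null) < X_null.shape[1]:
        raise ValueError("rank-deficient covariate design")
    try:
        beta0, _, ll0 = _logit_fit(X_null, y)
    except np.linalg.LinAlgError as e:
        raise ValueError("rank-deficient covariate design") from e

    degenerate_prs = np.ptp(prs) == 0.0
    if degenerate_prs:
        ll1, coef_prs, se_prs, p_model, coefs = ll0, 0.0, np.inf, 1.0, beta0
    else:
        X_full = np.column_stack([np.ones(n), prs] + ([C] if C.size else []))
        if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
            raise ValueError("rank-deficient full design")
        try:
            coefs, ses, ll1 = _logit_fit(X_full, y)
        except np.linalg.LinAlgError as e:
            raise ValueError("rank-deficient full design") from e
        coef_prs, se_prs = float(coefs[1]), float(ses[1])
        p_model = float(2.0 * norm.sf(abs(coef_prs / se_prs)))

    base_ll = _null_intercept_ll(y)
    r2_full = nagelkerke_r2(ll1, base_ll, n)
    r2_null = nagelkerke_r2(ll0, base_ll, n)
    r2_prs = max(r2_full - r2_null, 0.0)
    case_fraction = float(y.mean())
    adj = liability_adjust(r2_prs, case_fraction, prevalence)
    return ModelFit(
        loglik_full=ll1,
        loglik_null=ll0,
        n=n,
        coef_prs=coef_prs,
        se_prs=se_prs,
        r2_full=r2_full,
        r2_null=r2_null,
        r2_prs=r2_prs,
        r2_prs_adjusted=adj,
        p_model=p_model,
        coefficients=coefs,
    )


def _null_intercept_ll(y: np.ndarray) -> float:
    """Log-likelihood of the intercept-only model (baseline for both R2s)."""
    n = len(y)
    k = y.sum()
    p = k / n
    if p in (0.0, 1.0):
        return 0.0
    return float(k * np.log(p) + (n - k) * np.log(1.0 - p))


def default_threshold_grid(ceiling: float) -> np.ndarray:
    """Fine scan grid: 5e-8 plus additive 5e-5 steps up to the ceiling, and
    the ceiling itself."""
    ts = [GRID_FLOOR]
    t = GRID_FLOOR + FINE_STEP
    while t <= ceiling:
        ts.append(t)
        t += FINE_STEP
    if ceiling not in ts:
        ts.append(ceiling)
    return np.array(sorted(set(ts)))


@dataclass
class ScanResult:
    """Threshold-scan outcome plus the context the permutation test reuses:
    one precomputed score column per threshold (scores do not depend on the
    phenotype, so permutations only refit the logistic models)."""

    thresholds: np.ndarray
    table: pd.DataFrame
    best: ModelFit | None
    score_matrix: np.ndarray  # (n, T); NaN column where no SNP survived
    included_sets: list[list[HarmonizedVariant]] = field(default_factory=list)
    best_index: int | None = None


def threshold_scan(
    harmonized: list[HarmonizedVariant],
    clump_result: ClumpResult,
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates=None,
    ceiling: float = 1e-3,
    grid: np.ndarray | None = None,
    prevalence: float = DEFAULT_PREVALENCE,
) -> ScanResult:
    """Scan inclusion thresholds over the clumped variants and keep the fit
    maximizing ``r2_prs``.

    Thresholds with no surviving variant (or a failed fit) are recorded in
    the per-threshold table and skipped; the scan continues.
    """
    if grid is None:
        grid = default_threshold_grid(ceiling)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid > ceiling):
        raise ValueError("grid values must not exceed the ceiling")
    index_ids = {v.id for v in clump_result.index_variants}
    clumped = [
        h for h in harmonized if h.exclusion_reason is None and h.variant.id in index_ids
    ]
    clumped.sort(key=lambda h: h.p_value)
    pvals = np.array([h.p_value for h in clumped])

    n = len(phenotype)
    T = len(grid)
    score_matrix = np.full((n, T), np.nan)
    included_sets: list[list[HarmonizedVariant]] = []
    rows = []
    fits: list[ModelFit | None] = []
    for t_idx, t in enumerate(grid):
        k = int(np.searchsorted(pvals, t, side="right"))
        inc = clumped[:k]
        included_sets.append(inc)
        if k == 0:
            rows.append({"threshold": t, "n_snps": 0, "note": "no variant survives"})
            fits.append(None)
            continue
        prof = score(dosages, inc, threshold=t)
        score_matrix[:, t_idx] = prof.scores
        try:
            fit = fit_case_control(phenotype, prof.scores, covariates, prevalence)
        except (SeparationError, ValueError) as e:
            rows.append({"threshold": t, "n_snps": k, "note": str(e)})
            fits.append(None)
            continue
        fit.best_threshold = float(t)
        fit.n_snps = k
        fits.append(fit)
        rows.append(
            {
                "threshold": t,
                "n_snps": k,
                "r2_prs": fit.r2_prs,
                "r2_full": fit.r2_full,
                "r2_null": fit.r2_null,
                "coefficient": fit.coef_prs,
                "se": fit.se_prs,
                "p": fit.p_model,
                "note": "",
            }
        )
    best_index, best = None, None
    for t_idx, fit in enumerate(fits):
        if fit is not None and (best is None or fit.r2_prs > best.r2_prs):
            best_index, best = t_idx, fit
    return ScanResult(
        thresholds=grid,
        table=pd.DataFrame(rows),
        best=best,
        score_matrix=score_matrix,
        included_sets=included_sets,
        best_index=best_index,
    )


def empirical_p(
    scan: ScanResult,
    phenotype: np.ndarray,
    covariates=None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation significance of the best scanned model.

    For each permutation the phenotype labels are shuffled (covariates stay
    attached to their samples), the full threshold scan is refit, and the
    scan-minimum Wald p recorded; the empirical p is
    ``(#{permutation best p <= observed best p} + 1) / (n_perm + 1)``, with
    floor 1/(n_perm+1). Case/control counts are preserved exactly by
    construction (labels are permuted, never redrawn).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scan.best is None:
        raise ValueError("scan has no successful fit to permute")
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    C, _ = _covariate_matrix(covariates)
    designs = []
    for t_idx in range(len(scan.thresholds)):
        col = scan.score_matrix[:, t_idx]
        if np.isnan(col).all():
            continue
        designs.append(
            np.column_stack([np.ones(n), col] + ([C] if C.size else []))
        )
    observed = scan.best.p_model
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        best_p = np.inf
        for X in designs:
            try:
                coefs, ses, _ = _logit_fit(X, yp)
            except (SeparationError, np.linalg.LinAlgError):
                continue
            p = 2.0 * norm.sf(abs(coefs[1] / ses[1]))
            best_p = min(best_p, p)
        if best_p <= observed:
            hits += 1
    emp = (hits + 1) / (n_perm + 1)
    scan.best.empirical_p = emp
    return emp
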