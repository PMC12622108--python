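"""Scikit-learn-style estimator for clumping+thresholding PRS.

``ClumpThresholdPRS`` wraps the whole base-to-target pipeline behind the
fit/predict interface: ``fit`` harmonizes the base summary statistics to the
target variants, clumps on the training cohort's own LD, scans inclusion
thresholds for the fit maximizing the PRS-specific Nagelkerke R2, and stores
the resulting logistic model. ``decision_function`` returns the raw PRS;
``predict_proba`` the fitted case probabilities. The estimator composes with
sklearn model selection (get_params/set_params/clone).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .harmonize import clump, harmonize
from .scoring import (
    DEFAULT_PREVALENCE,
    empirical_p,
    score,
    threshold_scan,
)
from .types import SummaryStatRecord, VariantRecord

__all__ = ["ClumpThresholdPRS"]


class ClumpThresholdPRS(BaseEstimator, ClassifierMixin):
    """Clumping+thresholding polygenic risk score with logistic evaluation.

    Parameters
    ----------
    sumstats : list of SummaryStatRecord
        Base-GWAS effects (harmonized to the target inside ``fit``).
    variants : list of VariantRecord
        Target variant records aligned to the columns of X.
    window_kb, r2_max : clumping window (kb) and LD cut-off.
    p_ceiling : upper bound of the inclusion-threshold scan.
    n_perm : phenotype permutations for the empirical p (0 = skip).
    prevalence : population prevalence for the liability-scale adjustment.

    Attributes (after fit)
    ----------------------
    harmonized_, clump_, scan_ : intermediate pipeline stages.
    best_fit_ : ModelFit of the selected threshold.
    best_threshold_, n_snps_, coef_, intercept_ : selected-model summary.
    included_variants_ : the HarmonizedVariant list of the final model.
    """

    def __init__(
        self,
        sumstats: list[SummaryStatRecord] | None = None,
        variants: list[VariantRecord] | None = None,
        window_kb: float = 250.0,
        r2_max: float = 0.1,
        p_ceiling: float = 1e-3,
        threshold_grid: np.ndarray | None = None,
        n_perm: int = 0,
        prevalence: float = DEFAULT_PREVALENCE,
        random_state: int = 0,
    ):
        self.sumstats = sumstats
        self.variants = variants
        self.window_kb = window_kb
        self.r2_max = r2_max
        self.p_ceiling = p_ceiling
        self.threshold_grid = threshold_grid
        self.n_perm = n_perm
        self.prevalence = prevalence
        self.random_state = random_state

    def fit(self, X, y, covariates: pd.DataFrame | None = None):
        """Harmonize, clump, scan thresholds, and fit the logistic model.

        X is the (n_samples, n_variants) dosage matrix aligned to
        ``variants``; y the binary case status; ``covariates`` an optional
        per-sample frame entered in both the full and null models.
        """
        if self.sumstats is None or self.variants is None:
            raise ValueError("sumstats and variants are required to fit")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != len(y):
            raise ValueError("X and y disagree on sample count")
        if X.shape[1] != len(self.variants):
            raise ValueError("X and variants disagree on variant count")
        self.classes_ = np.unique(y)
        self.harmonized_ = harmonize(self.sumstats, self.variants)
        self.clump_ = clump(self.harmonized_, X, self.window_kb, self.r2_max)
        self.scan_ = threshold_scan(
            self.harmonized_,
            self.clump_,
            X,
            y,
            covariates,
            ceiling=self.p_ceiling,
            grid=self.threshold_grid,
            prevalence=self.prevalence,
        )
        if self.scan_.best is None:
            raise ValueError("no inclusion threshold produced a usable model")
        if self.n_perm:
            empirical_p(
                self.scan_, y, covariates, n_perm=self.n_perm,
                seed=self.random_state,
            )
        self.best_fit_ = self.scan_.best
        self.best_threshold_ = self.best_fit_.best_threshold
        self.n_snps_ = self.best_fit_.n_snps
        self.included_variants_ = self.scan_.included_sets[self.scan_.best_index]
        self.coef_ = self.best_fit_.coefficients
        self.intercept_ = float(self.coef_[0])
        self._covariate_cols = None if covariates is None else list(covariates.columns)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Raw PRS (weighted dosage sum over the selected variants)."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        return score(X, self.included_variants_).scores

    def predict_proba(self, X, covariates: pd.DataFrame | None = None) -> np.ndarray:
        """Fitted case probabilities from the selected logistic model."""
        self._check_fitted()
        prs = self.decision_function(X)
        parts = [np.ones(len(prs)), prs]
        if self._covariate_cols is not None:
            if covariates is None:
                raise ValueError("model was fitted with covariates; supply them")
            parts.append(covariates[self._covariate_cols].to_numpy(dtype=float))
        design = np.column_stack(parts)
        p1 = expit(design @ self.coef_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X, covariates: pd.DataFrame | None = None) -> np.ndarray:
        """Binary status at the fixed probability threshold 0.5."""
        return (self.predict_proba(X, covariates)[:, 1] > 0.5).astype(int)

    def _check_fitted(self):
        if not hasattr(self, "best_fit_"):
            raise RuntimeError("estimator is not fitted")
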