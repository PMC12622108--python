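"""Scoring, Nagelkerke decomposition, liability adjustment, threshold scan,
and permutation significance, each against an independent oracle."""
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import norm

from admixprs.harmonize import clump, harmonize
from admixprs.scoring import (
    SeparationError,
    default_threshold_grid,
    empirical_p,
    fit_case_control,
    liability_adjust,
    nagelkerke_r2,
    score,
    threshold_scan,
)
from admixprs.types import SummaryStatRecord, VariantRecord


def _harm(n, betas, pvals, chrom="1", spacing=10_000):
    ss = [
        SummaryStatRecord(
            VariantRecord(chrom, spacing * (j + 1), "G", "A"), float(betas[j]),
            float(pvals[j]),
        )
        for j in range(n)
    ]
    tv = [VariantRecord(chrom, spacing * (j + 1), "G", "A") for j in range(n)]
    return harmonize(ss, tv)


class TestScore:
    def test_zero_betas_give_zero_scores(self):
        h = _harm(3, [0, 0, 0], [0.1, 0.2, 0.3])
        d = np.random.default_rng(0).integers(0, 3, (10, 3)).astype(float)
        assert np.all(score(d, h).scores == 0.0)

    def test_single_snp_identity_weighting(self):
        h = _harm(1, [1.0], [0.5])
        d = np.array([[0.0], [1.0], [2.0]])
        assert list(score(d, h).scores) == [0.0, 1.0, 2.0]

    def test_linearity_in_betas(self):
        rng = np.random.default_rng(1)
        betas = rng.normal(size=5)
        p = rng.uniform(size=5)
        d = rng.integers(0, 3, (20, 5)).astype(float)
        s1 = score(d, _harm(5, betas, p)).scores
        s2 = score(d, _harm(5, 2 * betas, p)).scores
        np.testing.assert_allclose(s2, 2 * s1, rtol=1e-12)

    def test_variant_order_invariance(self):
        rng = np.random.default_rng(2)
        h = _harm(6, rng.normal(size=6), rng.uniform(size=6))
        d = rng.integers(0, 3, (15, 6)).astype(float)
        perm = rng.permutation(6)
        s1 = score(d, h).scores
        s2 = score(d, [h[i] for i in perm]).scores
        np.testing.assert_allclose(s1, s2, rtol=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            score(np.zeros((3, 1)), [])


class TestNagelkerke:
    def test_no_improvement_gives_zero(self):
        assert nagelkerke_r2(-10.0, -10.0, 20) == 0.0

    def test_strictly_below_one(self):
        assert nagelkerke_r2(-1e-6, -13.86, 20) < 1.0

    def test_non_nested_likelihoods_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            nagelkerke_r2(-11.0, -10.0, 20)

    def test_against_brute_force_ml(self):
        """10-observation fit: both likelihoods maximized by an independent
        scipy optimizer over the raw logistic log-likelihood."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 1], dtype=float)

        def nll(b, X):
            eta = X @ b
            return -(y @ eta - np.logaddexp(0, eta).sum())

        X1 = np.column_stack([np.ones(10), x])
        ll_full = -minimize(nll, np.zeros(2), args=(X1,), method="BFGS").fun
        ll_null = -minimize(nll, np.zeros(1), args=(np.ones((10, 1)),)).fun
        r2 = nagelkerke_r2(ll_full, ll_null, 10)
        cs = 1 - np.exp(2 * (ll_null - ll_full) / 10)
        expect = cs / (1 - np.exp(2 * ll_null / 10))
        assert r2 == pytest.approx(expect, abs=1e-6)
        fit = fit_case_control(y, x, covariates=None)
        assert fit.r2_full == pytest.approx(r2, abs=1e-6)


class TestLiabilityAdjust:
    def test_zero_preserved(self):
        assert liability_adjust(0.0, 0.47, 1.386e-4) == 0.0

    def test_unascertained_limit_is_pure_scale_factor(self):
        K = 0.01
        t = norm.isf(K)
        z = norm.pdf(t)
        expect = 0.1 * K * (1 - K) / z**2
        assert liability_adjust(0.1, K, K) == pytest.approx(expect, abs=1e-12)

    def test_closed_form_oracle(self):
        # independent transcription of the published transformation
        r2, P, K = 0.05, 0.4728, 1.386e-4
        t = norm.isf(K)
        z = norm.pdf(t)
        C = K * (1 - K) / z**2 * K * (1 - K) / (P * (1 - P))
        m = z / K
        theta = m * (P - K) / (1 - K) * (m * (P - K) / (1 - K) - t)
        expect = C * r2 / (1 + C * theta * r2)
        assert liability_adjust(r2, P, K) == pytest.approx(expect, abs=1e-9)

    def test_invalid_prevalence(self):
        with pytest.raises(ValueError):
            liability_adjust(0.1, 0.5, 0.0)


class TestFitCaseControl:
    def test_zero_prs_column(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 50)
        fit = fit_case_control(y, np.zeros(50), covariates=None)
        assert fit.r2_prs == 0.0 and fit.p_model == 1.0

    def test_matches_statsmodels(self):
        """Independent optimizer oracle: statsmodels Logit on the same
        12-row design agrees with the in-package Newton solver to 1e-6."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 12
        prs = rng.normal(size=n)
        cov = pd.DataFrame({"AGE": rng.normal(60, 8, n), "SEX": rng.integers(0, 2, n)})
        y = (rng.random(n) < 0.5).astype(float)
        y[:3] = 1  # ensure both classes
        y[-3:] = 0
        fit = fit_case_control(y, prs, cov)
        X = sm.add_constant(np.column_stack([prs, cov.to_numpy()]))
        ref = sm.Logit(y, X).fit(disp=0, method="newton")
        assert fit.coef_prs == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.se_prs == pytest.approx(ref.bse[1], abs=1e-6)
        assert fit.loglik_full == pytest.approx(ref.llf, abs=1e-6)

    def test_constant_covariate_rejected(self):
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError, match="constant covariate"):
            fit_case_control(y, np.arange(20.0), pd.DataFrame({"C": np.ones(20)}))

    def test_perfect_separation_reported(self):
        y = np.array([0] * 10 + [1] * 10)
        prs = np.array([-1.0] * 10 + [1.0] * 10)
        with pytest.raises(SeparationError):
            fit_case_control(y, prs, covariates=None)

    def test_decomposition_nonnegative(self, small_cohort, small_covariates):
        cohort, _ = small_cohort
        cov, _ = small_covariates
        rng = np.random.default_rng(6)
        fit = fit_case_control(cohort.phenotype, rng.normal(size=cohort.n_samples),
                               cov.loc[cohort.samples])
        assert fit.r2_full >= fit.r2_null
        assert fit.r2_prs == pytest.approx(fit.r2_full - fit.r2_null, abs=1e-12)


class TestThresholdScan:
    def test_default_grid_shape(self):
        g = default_threshold_grid(1e-3)
        assert g[0] == 5e-8 and g[-1] == 1e-3
        assert np.all(np.diff(g) > 0)
        # single-point grid at the strict genome-wide ceiling
        assert list(default_threshold_grid(5e-8)) == [5e-8]

    def test_single_threshold_grid_returned(self):
        rng = np.random.default_rng(7)
        n, m = 80, 10
        d = rng.integers(0, 3, (n, m)).astype(float)
        h = _harm(m, rng.normal(size=m), rng.uniform(1e-6, 1e-4, m))
        y = rng.integers(0, 2, n)
        cres = clump(h, d, 250, 0.5)
        res = threshold_scan(h, cres, d, y, ceiling=1e-3, grid=np.array([1e-4]))
        assert res.best.best_threshold == 1e-4

    def test_grid_beyond_ceiling_rejected(self):
        h = _harm(1, [0.1], [0.5])
        with pytest.raises(ValueError, match="ceiling"):
            threshold_scan(h, clump(h, np.zeros((4, 1)) + [[0], [1], [2], [1]],
                                    250, 0.5),
                           np.array([[0.0], [1.0], [2.0], [1.0]]),
                           np.array([0, 1, 0, 1]), ceiling=1e-3,
                           grid=np.array([1e-2]))

    def test_n_snps_monotone_in_threshold(self, small_cohort, small_harmonized,
                                          small_covariates):
        cohort, _ = small_cohort
        cov, _ = small_covariates
        d = cohort.dosages
        cres = clump(small_harmonized, d, 250, 0.5)
        res = threshold_scan(small_harmonized, cres, d, cohort.phenotype,
                             cov.loc[cohort.samples], ceiling=1e-3)
        ns = res.table["n_snps"].to_numpy()
        assert np.all(np.diff(ns) >= 0)

    def test_scan_selects_planted_causal_threshold(self):
        """5 causal + 50 null SNPs with planted p-values: the scan picks the
        causal-only inclusion set; oracle fits both candidate sets."""
        rng = np.random.default_rng(8)
        n = 400
        m = 55
        d = rng.binomial(2, 0.3, (n, m)).astype(float)
        betas = np.zeros(m)
        betas[:5] = 0.8
        eta = (d - d.mean(0)) @ betas
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        pvals = np.concatenate([
            np.full(5, 1e-7), rng.uniform(5e-4, 9e-4, 50)
        ])
        h = _harm(m, np.where(betas != 0, 0.8, rng.normal(0, 0.05, m)), pvals)
        cres = clump(h, d, 1, 0.99)  # tiny window: no absorption
        res = threshold_scan(h, cres, d, y, ceiling=1e-3,
                             grid=np.array([1e-6, 1e-3]))
        causal = [x for x in h if x.p_value < 1e-6]
        allsnp = list(h)
        r2 = {}
        for key, inc in (("causal", causal), ("all", allsnp)):
            fit = fit_case_control(y, score(d, inc).scores, None)
            r2[key] = fit.r2_prs
        expect = 1e-6 if r2["causal"] >= r2["all"] else 1e-3
        assert res.best.best_threshold == expect
        assert res.best.best_threshold == 1e-6  # planted design favours causal

    def test_empty_threshold_reported_scan_continues(self):
        rng = np.random.default_rng(9)
        h = _harm(4, rng.normal(size=4), [0.5, 0.6, 0.7, 0.8])
        d = rng.integers(0, 3, (60, 4)).astype(float)
        y = rng.integers(0, 2, 60)
        cres = clump(h, d, 250, 0.9)
        res = threshold_scan(h, cres, d, y, ceiling=1.0,
                             grid=np.array([1e-6, 0.9]))
        assert res.table.iloc[0]["n_snps"] == 0
        assert res.best is not None and res.best.n_snps == 4


class TestEmpiricalP:
    def _scan(self, seed=10, n=120, m=12, null=True):
        rng = np.random.default_rng(seed)
        d = rng.binomial(2, 0.4, (n, m)).astype(float)
        if null:
            y = rng.integers(0, 2, n)
            betas = rng.normal(size=m)
            pvals = rng.uniform(1e-5, 0.5, m)
        else:
            eta = (d - d.mean(0))[:, :4] @ np.full(4, 1.5)
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            betas = np.concatenate([np.full(4, 1.5), np.zeros(m - 4)])
            pvals = np.concatenate([np.full(4, 1e-5),
                                    rng.uniform(0.3, 0.5, m - 4)])
        h = _harm(m, betas, pvals)
        cres = clump(h, d, 1, 0.99)
        scan = threshold_scan(h, cres, d, y, ceiling=1.0,
                              grid=np.array([0.05, 0.2, 0.5]))
        return scan, y

    def test_floor_when_observed_beats_all(self):
        scan, y = self._scan(null=False)
        # strong signal: observed p far below anything 99 null permutations find
        p = empirical_p(scan, y, n_perm=99, seed=1)
        assert p == pytest.approx(1 / 100)
        assert scan.best.empirical_p == p

    def test_boundary_single_permutation(self):
        scan, y = self._scan(seed=11)
        p = empirical_p(scan, y, n_perm=1, seed=2)
        assert p in (0.5, 1.0)

    def test_floor_value_mirrors_reference_protocol(self):
        # 10,000 permutations put the attainable floor at ~1.0e-4
        assert 1 / (10_000 + 1) == pytest.approx(1.0e-4, rel=1e-2)
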