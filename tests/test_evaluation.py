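"""ROC/AUC, DeLong, confusion metrics, predictive values, split protocol."""
import numpy as np
import pytest
from scipy.stats import norm

from admixprs.evaluation import (
    auc,
    confusion_at,
    delong_test,
    multi_split_stability,
    predictive_values,
    split_cohort,
)


class TestAuc:
    def test_perfect_separation(self):
        s = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1])
        assert auc(s, y).auc == 1.0

    def test_all_ties_give_half(self):
        assert auc(np.ones(10), np.array([0, 1] * 5)).auc == 0.5

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(1)
        s = np.round(rng.normal(size=12), 1)  # induce some ties
        y = np.array([1] * 6 + [0] * 6)
        total = 0.0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                total += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
        assert auc(s, y).auc == pytest.approx(total / 36, abs=1e-12)

    def test_matches_sklearn_on_larger_sample(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s = rng.normal(size=200) + y
        assert auc(s, y).auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.normal(size=100)
        assert auc(np.exp(3 * s), y).auc == pytest.approx(auc(s, y).auc, abs=1e-12)

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        r = auc(rng.normal(size=80) + 0.5 * y, y)
        assert r.ci_low <= r.auc <= r.ci_high

    def test_closed_form_binormal_auc(self):
        """control~N(0,1), case~N(delta,1) => AUC = Phi(delta/sqrt(2))."""
        rng = np.random.default_rng(5)
        delta = 0.8
        n = 20_000
        y = np.repeat([0, 1], n // 2)
        s = rng.normal(size=n) + delta * y
        expect = norm.cdf(delta / np.sqrt(2))
        assert auc(s, y).auc == pytest.approx(expect, abs=0.015)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc(np.arange(4.0), np.ones(4, dtype=int))


class TestDeLong:
    def test_self_comparison_p_one(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.normal(size=50)
        with pytest.warns(UserWarning, match="zero variance"):
            z, p = delong_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 120)
        y[:2] = [0, 1]
        a = rng.normal(size=120) + 0.8 * y
        b = rng.normal(size=120) + 0.3 * y
        z1, p1 = delong_test(a, b, y)
        z2, p2 = delong_test(b, a, y)
        assert z1 == pytest.approx(-z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_variance_matches_bootstrap(self):
        """DeLong variance of the AUC difference on correlated scores vs a
        2,000-replicate bootstrap estimate (relative error < 15%)."""
        rng = np.random.default_rng(8)
        n = 500
        y = np.repeat([0, 1], n // 2)
        latent = rng.normal(size=n)
        a = latent + 0.6 * y + 0.5 * rng.normal(size=n)
        b = latent + 0.3 * y + 0.5 * rng.normal(size=n)
        # analytic variance from the implementation's own z statistic
        z, _ = delong_test(a, b, y)
        d_obs = auc(a, y).auc - auc(b, y).auc
        var_delong = (d_obs / z) ** 2

        boot = []
        for _ in range(2000):
            idx = np.concatenate([
                rng.choice(np.flatnonzero(y == 0), n // 2),
                rng.choice(np.flatnonzero(y == 1), n // 2),
            ])
            boot.append(auc(a[idx], y[idx]).auc - auc(b[idx], y[idx]).auc)
        var_boot = np.var(boot, ddof=1)
        assert abs(var_delong - var_boot) / var_boot < 0.15

    def test_detects_better_model(self):
        rng = np.random.default_rng(9)
        n = 400
        y = np.repeat([0, 1], n // 2)
        good = rng.normal(size=n) + 1.2 * y
        bad = rng.normal(size=n)
        z, p = delong_test(good, bad, y)
        assert z > 0 and p < 1e-4


class TestConfusion:
    def test_degenerate_classifier(self):
        y = np.array([1, 1, 0, 0])
        p = np.array([0.9, 0.9, 0.9, 0.9])
        m = confusion_at(p, y)
        assert m.sensitivity == 1.0 and m.specificity == 0.0
        assert m.balanced_accuracy == 0.5

    def test_default_threshold_is_half(self):
        m = confusion_at(np.array([0.4, 0.6]), np.array([0, 1]))
        assert m.threshold == 0.5

    def test_hand_computed_two_by_two(self):
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        p = np.array([0.9, 0.8, 0.3, 0.6, 0.2, 0.7, 0.1, 0.4, 0.55, 0.05])
        m = confusion_at(p, y)
        # hand table: TP=3 FN=1 TN=4 FP=2
        assert m.sensitivity == pytest.approx(3 / 4)
        assert m.specificity == pytest.approx(4 / 6)
        assert m.accuracy == pytest.approx(7 / 10)
        assert m.balanced_accuracy == pytest.approx((3 / 4 + 4 / 6) / 2)


class TestPredictiveValues:
    def test_perfect_classifier(self):
        s = np.array([10.0] * 5 + [0.0] * 95)
        y = np.array([1] * 5 + [0] * 95)
        pv = predictive_values(s, y, 0.05, 0.3)
        assert pv.ppv == pytest.approx(1.0) and pv.npv == pytest.approx(1.0)

    def test_bayes_formula_oracle(self):
        """sens = spec = 0.5 at the global PD prevalence: NPV from direct
        Bayes arithmetic, and it exceeds 0.99."""
        K = 1.386e-4
        sens = spec = 0.5
        npv = spec * (1 - K) / (spec * (1 - K) + (1 - sens) * K)
        assert npv > 0.99
        rng = np.random.default_rng(10)
        n = 2000
        y = rng.integers(0, 2, n)
        s = rng.normal(size=n)  # uninformative scores: sens+spec ~ 1
        pv = predictive_values(s, y, 0.2, K)
        assert pv.npv > 0.99

    def test_flagged_fraction_exact_under_ties(self):
        s = np.ones(100)
        y = np.array([0, 1] * 50)
        pv = predictive_values(s, y, 0.1, 0.01, [f"S{i}" for i in range(100)])
        assert pv.n_flagged == 10

    def test_npv_monotone_in_specificity_grid(self):
        K = 1.386e-4
        for sens in np.linspace(0.0, 1.0, 6):
            last = -1.0
            for spec in np.linspace(0.05, 1.0, 8):
                npv = spec * (1 - K) / (spec * (1 - K) + (1 - sens) * K)
                assert npv >= last
                assert npv > 0.99
                last = npv


class TestSplit:
    def test_reference_sizes(self):
        ids = [f"S{i}" for i in range(1398)]
        plan = split_cohort(ids, 0.7, seed=0)
        assert len(plan.train_ids) == 979
        assert len(plan.valid_ids) == 419

    def test_disjoint_union(self):
        ids = [f"S{i}" for i in range(101)]
        plan = split_cohort(ids, 0.7, seed=1)
        assert set(plan.train_ids) | set(plan.valid_ids) == set(ids)
        assert not set(plan.train_ids) & set(plan.valid_ids)

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_cohort(["a", "b", "c"], 0.99, seed=0)

    def test_seed_changes_membership_not_sizes(self):
        ids = [f"S{i}" for i in range(100)]
        p1 = split_cohort(ids, 0.7, seed=1)
        p2 = split_cohort(ids, 0.7, seed=2)
        assert len(p1.train_ids) == len(p2.train_ids)
        assert set(p1.train_ids) != set(p2.train_ids)
        assert split_cohort(ids, 0.7, seed=1) == p1


class TestMultiSplit:
    def test_identical_seeds_zero_sd(self):
        ids = [f"S{i}" for i in range(50)]
        rng = np.random.default_rng(11)
        scores = {s: rng.normal() for s in ids}

        def run(plan):
            return float(np.mean([scores[s] for s in plan.valid_ids]))

        df, mean, sd = multi_split_stability(run, ids, k=5, seeds=[3] * 5)
        assert sd == 0.0 and len(df) == 5

    def test_errors_reported_per_split(self):
        ids = [f"S{i}" for i in range(40)]

        def run(plan):
            if plan.seed == 1:
                raise ValueError("single-class validation set")
            return 0.6

        df, mean, sd = multi_split_stability(run, ids, k=3, seeds=[0, 1, 2])
        assert df["error"].str.contains("single-class").sum() == 1
        assert mean == pytest.approx(0.6)
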