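"""ROC, rank-sum, correlation and cross-validation against exhaustive
oracles and closed-form cases."""

import numpy as np
import pytest

from ngtdmpet import (
    apply_threshold,
    cross_validated_auc,
    make_cv_plan,
    pearson_correlation,
    roc_analysis,
    wilcoxon_rank_sum,
)

from _oracles import auc_pair_count, ranksum_exact_enumeration


class TestRoc:
    def test_perfect_separation(self):
        s = roc_analysis(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1], bool))
        assert s.auc == pytest.approx(1.0)
        assert s.sensitivity == 1.0 and s.specificity == 1.0
        assert s.accuracy == 1.0

    def test_anti_separation_auto_flips(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([0, 0, 1, 1], bool)
        forced = roc_analysis(scores, y, orientation="higher")
        assert forced.auc == pytest.approx(0.0)
        flipped = roc_analysis(scores, y, orientation="auto")
        assert flipped.auc == pytest.approx(1.0)
        assert not flipped.higher_is_malignant
        assert apply_threshold(scores, flipped).tolist() == [False, False, True, True]

    def test_ties_match_pair_count(self):
        scores = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        y = np.array([0, 1, 0, 1, 1], bool)
        s = roc_analysis(scores, y, orientation="higher")
        assert s.auc == pytest.approx(auc_pair_count(scores, y))

    def test_random_cohorts_match_pair_count(self, rng):
        """Trapezoidal AUC equals the exhaustive Mann-Whitney count on
        small cohorts, with and without ties."""
        for _ in range(200):
            n = int(rng.integers(4, 13))
            y = np.zeros(n, bool)
            y[: int(rng.integers(1, n))] = True
            rng.shuffle(y)
            scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            if y.all() or not y.any():
                continue
            s = roc_analysis(scores, y, orientation="higher")
            assert s.auc == pytest.approx(auc_pair_count(scores, y), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        y = rng.random(40) > 0.6
        if y.all() or not y.any():
            y[:3] = [True, False, True]
        scores = rng.normal(size=40)
        a = roc_analysis(scores, y, orientation="higher").auc
        b = roc_analysis(np.exp(scores * 2), y, orientation="higher").auc
        assert a == pytest.approx(b)

    def test_flip_symmetry(self, rng):
        y = np.array([0, 1] * 10, bool)
        scores = rng.normal(size=20)
        a = roc_analysis(scores, y, orientation="higher").auc
        b = roc_analysis(-scores, y, orientation="higher").auc
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(np.array([1.0, 2.0]), np.array([True, True]))

    def test_threshold_rule_reproduces_operating_point(self, rng):
        for _ in range(20):
            y = rng.random(30) > 0.5
            if y.all() or not y.any():
                continue
            scores = rng.normal(size=30) + y * 0.8
            s = roc_analysis(scores, y)
            pred = apply_threshold(scores, s)
            tp = (pred & y).sum()
            tn = (~pred & ~y).sum()
            assert tp / y.sum() == pytest.approx(s.sensitivity)
            assert tn / (~y).sum() == pytest.approx(s.specificity)
            assert (tp + tn) / y.size == pytest.approx(s.accuracy)


class TestWilcoxon:
    def test_extreme_ranks_exact(self):
        """a=[1,2,3] vs b=[4,5,6]: 2 of C(6,3)=20 assignments are as
        extreme, so the two-sided exact p is 0.1."""
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.1)

    def test_identical_groups(self):
        res = wilcoxon_rank_sum([5, 5, 5], [5, 5, 5])
        assert res.pvalue == 1.0

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n_a = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 6))
            a = rng.integers(0, 8, n_a).astype(float)  # ties likely
            b = rng.integers(0, 8, n_b).astype(float)
            mine = wilcoxon_rank_sum(a, b, method="exact").pvalue
            ref = ranksum_exact_enumeration(a.tolist(), b.tolist())
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_close_to_exact(self, rng):
        """Tie-corrected normal approximation tracks the exact
        enumeration within 0.01 for groups of 10+."""
        for _ in range(15):
            a = rng.normal(size=10)
            b = rng.normal(loc=rng.uniform(-1, 1), size=12)
            exact = wilcoxon_rank_sum(a, b, method="exact").pvalue
            approx = wilcoxon_rank_sum(a, b, method="normal").pvalue
            assert abs(exact - approx) < 0.01


class TestPearson:
    def test_known_values(self):
        r, _ = pearson_correlation([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0)
        r, _ = pearson_correlation([1, 2, 3], [-1, -2, -3])
        assert r == pytest.approx(-1.0)
        r, _ = pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestCvPlan:
    def test_116_lesions_11_folds_sizes(self):
        """116 = 6*11 + 5*10: six folds of 11 and five of 10."""
        ids = [f"L{i}" for i in range(116)]
        labels = ["benign"] * 35 + ["malignant"] * 81
        plan = make_cv_plan(ids, labels, n_folds=11, seed=3)
        sizes = sorted(plan.fold_sizes())
        assert sizes == [10] * 5 + [11] * 6
        # coverage: every lesion in exactly one test fold
        all_test = [i for f in range(11) for i in plan.test_ids(f)]
        assert sorted(all_test) == sorted(ids)

    def test_stratification_balances_classes(self):
        ids = [f"L{i}" for i in range(116)]
        labels = ["benign"] * 35 + ["malignant"] * 81
        plan = make_cv_plan(ids, labels, n_folds=11, seed=0)
        benign_per_fold = [
            sum(1 for i in plan.test_ids(f) if labels[ids.index(i)] == "benign")
            for f in range(11)
        ]
        assert max(benign_per_fold) - min(benign_per_fold) <= 1

    def test_reproducible_and_seed_sensitive(self):
        ids = [f"L{i}" for i in range(40)]
        labels = ["benign", "malignant"] * 20
        a = make_cv_plan(ids, labels, 11, seed=5)
        b = make_cv_plan(ids, labels, 11, seed=5)
        c = make_cv_plan(ids, labels, 11, seed=6)
        assert a.fold_of == b.fold_of
        assert a.fold_of != c.fold_of

    def test_leave_one_out(self):
        ids = [f"L{i}" for i in range(11)]
        labels = ["benign"] * 5 + ["malignant"] * 6
        plan = make_cv_plan(ids, labels, n_folds=11, seed=1)
        assert sorted(plan.fold_sizes()) == [1] * 11

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_cv_plan(["a", "b"], ["benign", "malignant"], n_folds=3, seed=0)

    def test_unstratified_sizes(self):
        ids = [f"L{i}" for i in range(116)]
        labels = ["benign"] * 35 + ["malignant"] * 81
        plan = make_cv_plan(ids, labels, 11, seed=0, stratified=False)
        assert sorted(plan.fold_sizes()) == [10] * 5 + [11] * 6


class TestCrossValidation:
    def _cohort(self, rng, n=66, separation=3.0):
        ids = [f"L{i}" for i in range(n)]
        y = {i: k < n // 3 for k, i in enumerate(ids)}
        scores = {
            i: rng.normal(loc=separation if y[i] else 0.0) for i in ids
        }
        labels = ["malignant" if y[i] else "benign" for i in ids]
        return ids, labels, y, scores

    def test_separable_feature_perfect_transfer(self, rng):
        """A perfectly separating feature transfers its training
        threshold with no test errors.  The threshold sits at the lowest
        malignant training score, so exact transfer needs the malignant
        floor to be stable across folds (two-level scores here)."""
        ids, labels, y, _ = self._cohort(rng)
        scores = {i: 2.0 if y[i] else 0.0 for i in ids}
        plan = make_cv_plan(ids, labels, 11, seed=2)
        res = cross_validated_auc(scores, y, plan)
        assert res.mean_sensitivity == pytest.approx(1.0)
        assert res.mean_specificity == pytest.approx(1.0)

    def test_noise_feature_at_chance(self, rng):
        """A pure-noise feature carries no signal: the corner operating
        point balances sensitivity and specificity, so transferred
        accuracy sits at chance (~0.5) regardless of class imbalance."""
        accs = []
        for seed in range(6):
            r = np.random.default_rng(seed)
            ids = [f"L{i}" for i in range(120)]
            y = {i: k < 80 for k, i in enumerate(ids)}
            labels = ["malignant" if y[i] else "benign" for i in ids]
            scores = {i: r.normal() for i in ids}
            plan = make_cv_plan(ids, labels, 11, seed=seed)
            accs.append(cross_validated_auc(scores, y, plan).mean_accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.08

    def test_fold_coverage(self, rng):
        ids, labels, y, scores = self._cohort(rng)
        plan = make_cv_plan(ids, labels, 11, seed=4)
        res = cross_validated_auc(scores, y, plan)
        assert len(res.fold_summaries) == 11
        assert not res.skipped_folds
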