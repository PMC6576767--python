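"""Cross-validation, AUC, permutation tests, and BH FDR contracts."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from langdx.errors import InvalidParameterError, UndefinedAUCError
from langdx.evaluation import (
    auc,
    bh_fdr,
    cross_validated_scores,
    perm_test_auc_diff,
    perm_test_auc_vs_chance,
    stratified_kfold,
)


def brute_force_auc(scores, labels):
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestStratifiedKFold:
    def test_exact_divisibility(self):
        y = np.array([1] * 20 + [0] * 80)
        folds = stratified_kfold(y, k=10, seed=0)
        for f in range(10):
            test = folds.fold_of == f
            assert test.sum() == 10
            assert y[test].sum() == 2

    def test_partition_covers_everything_disjointly(self):
        rng = np.random.default_rng(1)
        y = (rng.random(103) < 0.3).astype(int)
        folds = stratified_kfold(y, k=7, seed=1)
        assert set(folds.fold_of) == set(range(7))
        sizes = np.bincount(folds.fold_of)
        assert sizes.sum() == 103 and sizes.max() - sizes.min() <= 1
        case_counts = [y[folds.fold_of == f].sum() for f in range(7)]
        assert max(case_counts) - min(case_counts) <= 1

    def test_k_reduced_with_warning(self):
        y = np.array([1] * 9 + [0] * 91)
        with pytest.warns(UserWarning, match="reducing k"):
            folds = stratified_kfold(y, k=10, seed=2)
        assert folds.k == 9

    def test_invalid_k_rejected(self):
        with pytest.raises(InvalidParameterError):
            stratified_kfold(np.array([0, 1, 0, 1]), k=1)

    def test_deterministic_under_seed(self):
        y = np.tile([0, 0, 1], 30)
        a = stratified_kfold(y, k=5, seed=7)
        b = stratified_kfold(y, k=5, seed=7)
        assert np.array_equal(a.fold_of, b.fold_of)


class TestAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 1.0),
            ([0.3, 0.3, 0.3, 0.3], [1, 0, 1, 0], 0.5),
            ([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], 0.75),
        ],
    )
    def test_examples(self, scores, labels, expected):
        assert auc(np.array(scores), np.array(labels)) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            auc(np.array([0.1, 0.2]), np.array([1, 1]))

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = rng.integers(0, 6, n).astype(float)  # heavy ties
        labels = np.zeros(n, int)
        labels[rng.choice(n, int(rng.integers(1, n)), replace=False)] = 1
        if labels.sum() in (0, n):
            return
        assert abs(auc(scores, labels) - brute_force_auc(scores, labels)) < 1e-12


class TestPermTestAucDiff:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(0)
        s = rng.random(30)
        y = np.tile([0, 1], 15)
        assert perm_test_auc_diff(s, s, y, n_iter=200, seed=1) == 1.0

    def test_add_one_smoothing_lower_bound(self):
        rng = np.random.default_rng(1)
        y = np.repeat([1, 0], 25)
        a = y + rng.normal(0, 0.05, 50)  # near-perfect model
        b = rng.random(50)
        p = perm_test_auc_diff(a, b, y, n_iter=500, seed=2)
        assert p >= 1 / 501

    def test_deterministic_and_validates_alignment(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(40), rng.random(40)
        y = np.tile([0, 1], 20)
        assert perm_test_auc_diff(a, b, y, 300, seed=3) == perm_test_auc_diff(a, b, y, 300, seed=3)
        with pytest.raises(InvalidParameterError):
            perm_test_auc_diff(a[:-1], b, y, 300, seed=0)


class TestPermTestAucVsChance:
    def test_perfect_separation_minimal_p(self):
        # no label permutation can beat AUC 1.0 (identity permutation aside,
        # astronomically unlikely among C(40,20) arrangements)
        y = np.repeat([0, 1], 20)
        s = np.linspace(0, 1, 40)
        assert perm_test_auc_vs_chance(s, y, n_iter=999, seed=4) == pytest.approx(1 / 1000)

    def test_requires_at_least_one_iteration(self):
        with pytest.raises(InvalidParameterError):
            perm_test_auc_vs_chance(np.array([0.1, 0.9]), np.array([0, 1]), n_iter=0)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(80):
            s = rng.random(60)
            y = np.zeros(60, int)
            y[rng.choice(60, 20, replace=False)] = 1
            pvals.append(perm_test_auc_vs_chance(s, y, n_iter=400, seed=int(rng.integers(2**31))))
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01


class TestBhFdr:
    def test_worked_example_all_rejected(self):
        rejected, adjusted = bh_fdr([0.01, 0.02, 0.04, 0.05], alpha=0.05)
        assert rejected.all()
        assert adjusted[-1] == pytest.approx(0.05)

    def test_all_ones_none_rejected(self):
        rejected, adjusted = bh_fdr([1.0, 1.0, 1.0])
        assert not rejected.any()
        assert (adjusted == 1.0).all()

    def test_single_test_reduces_to_alpha_threshold(self):
        assert bh_fdr([0.049])[0].all()
        assert not bh_fdr([0.051])[0].any()

    def test_invalid_values_rejected(self):
        with pytest.raises(InvalidParameterError):
            bh_fdr([0.1, 1.5])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(6)
        p = rng.random(15)
        _, adjusted = bh_fdr(p)
        assert (adjusted >= p - 1e-15).all()


class TestCrossValidatedScores:
    @staticmethod
    def _inputs(n, seed, signal=0.0):
        rng = np.random.default_rng(seed)
        topic_scores = rng.dirichlet(np.ones(5), size=n)
        grams = sp.csr_matrix(rng.random((n, 30)) * (rng.random((n, 30)) < 0.3))
        demo = rng.normal(size=(n, 3))
        eta = signal * topic_scores[:, 0] - signal * 0.2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return topic_scores, grams, demo, y

    def test_every_row_predicted_exactly_once_out_of_fold(self):
        topic_scores, grams, demo, y = self._inputs(120, 0)
        folds = stratified_kfold(y, k=6, seed=1)
        cv = cross_validated_scores(
            topic_scores, grams, demo, y, folds,
            k_grams=10, n_estimators=20, seed=2,
        )
        for vec in (cv.p_language, cv.p_demographics, cv.p_combined):
            assert not np.isnan(vec).any()
            assert ((vec >= 0) & (vec <= 1)).all()
        assert not cv.skipped_folds

    def test_null_data_auc_near_chance(self):
        topic_scores, grams, demo, y = self._inputs(1000, 3)
        folds = stratified_kfold(y, k=10, seed=4)
        cv = cross_validated_scores(
            topic_scores, grams, demo, y, folds,
            k_grams=15, n_estimators=50, seed=5,
        )
        for vec in (cv.p_language, cv.p_demographics, cv.p_combined):
            assert abs(auc(vec, y) - 0.5) < 0.06

    def test_strong_planted_topic_dominates_demographics(self):
        topic_scores, grams, demo, y = self._inputs(600, 6, signal=14.0)
        folds = stratified_kfold(y, k=10, seed=7)
        cv = cross_validated_scores(
            topic_scores, grams, demo, y, folds,
            k_grams=15, n_estimators=100, seed=8,
        )
        assert auc(cv.p_language, y) - auc(cv.p_demographics, y) > 0.1
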