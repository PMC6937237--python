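"""Grouped nested CV, F screening, balanced accuracy, AUPRC, chance runs."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score, balanced_accuracy_score

from rgpipe.classify import (
    Sample,
    auprc,
    auprc_multiclass,
    balanced_accuracy,
    chance_run,
    f_statistic,
    make_folds,
    nested_cv,
    select_top_features,
)


def make_samples(X, y, pids=None):
    pids = pids or [f"P{i}" for i in range(len(y))]
    return [Sample(p, p, lab, X[i : i + 1]) for i, (p, lab) in enumerate(zip(pids, y))]


class TestFolds:
    def test_partition_property(self):
        pids = [f"P{i}" for i in range(23)]
        labels = [i % 2 for i in range(23)]
        plan = make_folds(pids, labels, k=5, seed=0)
        tests = [set(te) for _, te in plan.outer_folds]
        assert set().union(*tests) == set(pids)
        for a, b in itertools.combinations(tests, 2):
            assert not (a & b)
        for tr, te in plan.outer_folds:
            assert not (set(tr) & set(te))
            assert set(tr) | set(te) == set(pids)

    def test_leave_one_patient_out(self):
        pids = [f"P{i}" for i in range(6)]
        plan = make_folds(pids, [0, 1] * 3, k=6, seed=0, stratified=False)
        assert all(len(te) == 1 for _, te in plan.outer_folds)

    def test_seed_reuse_reproduces_folds(self):
        pids = [f"P{i}" for i in range(20)]
        labels = [i % 2 for i in range(20)]
        a = make_folds(pids, labels, k=4, seed=7)
        b = make_folds(pids, labels, k=4, seed=7)
        assert a.outer_folds == b.outer_folds and a.inner_folds == b.inner_folds

    def test_small_class_falls_back_with_warning(self):
        pids = [f"P{i}" for i in range(10)]
        labels = [0] * 8 + [1] * 2
        with pytest.warns(UserWarning):
            plan = make_folds(pids, labels, k=5, seed=0)
        assert plan.k == 5

    def test_inner_folds_stay_inside_outer_training_set(self):
        pids = [f"P{i}" for i in range(20)]
        plan = make_folds(pids, [i % 2 for i in range(20)], k=4, seed=1)
        for (train, _), inner in zip(plan.outer_folds, plan.inner_folds):
            for itr, iva in inner:
                assert set(itr) <= set(train) and set(iva) <= set(train)
                assert not (set(itr) & set(iva))


class TestFStatistic:
    def test_flat_feature_zero(self):
        X = np.ones((6, 3))
        X[:, 1] = [1, 2, 3, 4, 5, 6]
        F = f_statistic(X, [0, 0, 0, 1, 1, 1])
        assert F[0] == 0 and F[2] == 0 and F[1] > 0

    def test_hand_anova(self):
        """Classes {1,2} vs {3,4}: SSB = 4, SSW = 1, df (1, 2), F = 8."""
        F = f_statistic(np.array([[1.0], [2.0], [3.0], [4.0]]), [0, 0, 1, 1])
        assert F[0] == pytest.approx(8.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(np.ones((3, 2)), [0, 0, 0])

    def test_top_m_selection_stable_ties(self):
        F = np.array([1.0, 3.0, 3.0, 0.5, 3.0])
        assert select_top_features(F, 2).tolist() == [1, 2]
        assert select_top_features(F, 10).tolist() == [0, 1, 2, 3, 4]


class TestBalancedAccuracy:
    def test_hand_confusion(self):
        assert balanced_accuracy(np.array([[2, 0], [1, 1]])) == pytest.approx(0.75)

    def test_diagonal_is_one(self):
        assert balanced_accuracy(np.diag([3, 7, 2])) == 1.0

    def test_balanced_classes_equals_plain_accuracy(self, rng):
        y = np.repeat([0, 1, 2], 20)
        pred = rng.integers(0, 3, size=60)
        cm = np.zeros((3, 3), int)
        for t, p in zip(y, pred):
            cm[t, p] += 1
        assert balanced_accuracy(cm) == pytest.approx(np.mean(y == pred))

    def test_empty_class_row_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.array([[2, 0], [0, 0]]))


def brute_force_auprc(scores, positives):
    """Independent oracle: enumerate thresholds, sum precision * recall step."""
    scores = np.asarray(scores, float)
    positives = np.asarray(positives, bool)
    n_pos = positives.sum()
    ap, prev_recall = 0.0, 0.0
    for thr in sorted(set(scores), reverse=True):
        kept = scores >= thr
        tp = int((kept & positives).sum())
        precision = tp / kept.sum()
        recall = tp / n_pos
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


class TestAUPRC:
    def test_perfect_ranking(self):
        assert auprc([3, 2, 1, 0], [True, True, False, False]) == 1.0

    def test_hand_example(self):
        assert auprc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(5 / 6)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            auprc([1, 2], [False, False])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        scores=st.lists(st.integers(0, 5), min_size=2, max_size=8),
        labels=st.lists(st.booleans(), min_size=2, max_size=8),
    )
    def test_matches_brute_force_and_sklearn(self, scores, labels):
        n = min(len(scores), len(labels))
        scores, labels = scores[:n], labels[:n]
        if not (0 < sum(labels) < n):
            return
        ours = auprc(scores, labels)
        assert ours == pytest.approx(brute_force_auprc(scores, labels), abs=1e-8)
        assert ours == pytest.approx(
            average_precision_score(labels, np.asarray(scores, float)), abs=1e-8
        )

    def test_multiclass_is_mean_of_one_vs_rest(self):
        rngl = np.random.default_rng(0)
        D = rngl.normal(size=(12, 3))
        y = np.repeat([0, 1, 2], 4)
        expect = np.mean([auprc(D[:, c], y == c) for c in range(3)])
        assert auprc_multiclass(D, y, [0, 1, 2]) == pytest.approx(expect)


class TestNestedCV:
    def _separable(self, n=24, n_classes=2, n_features=10, seed=0):
        rngl = np.random.default_rng(seed)
        y = np.arange(n) % n_classes
        X = rngl.normal(size=(n, n_features))
        X[:, 0] += 10 * y  # perfectly separating feature
        return make_samples(X, list(y))

    def test_perfectly_separable_scores_one(self):
        samples = self._separable()
        plan = make_folds([s.patient_id for s in samples], [s.label for s in samples],
                          k=4, seed=0)
        res = nested_cv(samples, plan, cost_grid=(1.0,))
        assert res.mean_accuracy == 1.0
        assert all(f.auprc == 1.0 for f in res.per_fold)

    def test_shuffled_labels_near_chance(self):
        rngl = np.random.default_rng(42)
        n = 60
        X = rngl.normal(size=(n, 5))
        y = rngl.permutation(np.arange(n) % 3)
        samples = make_samples(X, list(y))
        plan = make_folds([s.patient_id for s in samples], list(y), k=5, seed=1)
        res = nested_cv(samples, plan, cost_grid=(1.0,))
        assert abs(res.mean_accuracy - 1 / 3) < 0.18

    def test_no_leakage_from_test_rows(self):
        """Perturbing test-fold feature rows changes nothing fit on training."""
        rngl = np.random.default_rng(3)
        n = 20
        X = rngl.normal(size=(n, 30))
        y = list(np.arange(n) % 2)
        samples = make_samples(X, y)
        plan = make_folds([s.patient_id for s in samples], y, k=4, seed=0)
        res_a = nested_cv(samples, plan, m_select=10, cost_grid=(0.1, 1.0))
        # scramble the rows of every test patient, fold by fold
        perturbed = [
            Sample(s.uid, s.patient_id, s.label, s.matrix + 100 * rngl.normal(size=s.matrix.shape),
                   s.center_row)
            for s in samples
        ]
        by_pid = {s.patient_id: s for s in perturbed}
        for fold_i, (train_pids, test_pids) in enumerate(plan.outer_folds):
            mixed = [s if s.patient_id in train_pids else by_pid[s.patient_id] for s in samples]
            res_b = nested_cv(mixed, plan, m_select=10, cost_grid=(0.1, 1.0))
            assert np.array_equal(
                res_a.per_fold[fold_i].selected_feature_indices,
                res_b.per_fold[fold_i].selected_feature_indices,
            )
            assert np.allclose(res_a.per_fold[fold_i].coef, res_b.per_fold[fold_i].coef)
            assert res_a.per_fold[fold_i].chosen_cost == res_b.per_fold[fold_i].chosen_cost

    def test_augmented_views_stay_with_their_patient(self):
        """Multi-row samples are assigned to folds whole, never split."""
        rngl = np.random.default_rng(5)
        samples = [
            Sample(f"P{i}", f"P{i}", i % 2, rngl.normal(size=(4, 6)), center_row=0)
            for i in range(12)
        ]
        plan = make_folds([s.patient_id for s in samples], [s.label for s in samples],
                          k=3, seed=2)
        res = nested_cv(samples, plan, cost_grid=(1.0,))
        assert len(res.per_fold) == 3  # runs; grouping is structural (by patient id)

    def test_missing_center_row_rejected(self):
        with pytest.raises(ValueError):
            Sample("a", "a", 0, np.zeros((2, 3)), center_row=5)


class TestChanceRun:
    def test_three_balanced_classes_near_third(self):
        rngl = np.random.default_rng(0)
        n = 45
        ages = rngl.normal(50, 10, size=(n, 1))
        samples = [Sample(f"P{i}", f"P{i}", i % 3, ages[i : i + 1]) for i in range(n)]
        accs = chance_run(samples, n_repeats=5, seed=1, k=5, cost_grid=(1.0,))
        assert accs.shape == (5, 5)
        assert abs(accs.mean() - 1 / 3) < 0.12

    def test_two_balanced_classes_near_half(self):
        rngl = np.random.default_rng(0)
        n = 40
        ages = rngl.normal(50, 10, size=(n, 1))
        samples = [Sample(f"P{i}", f"P{i}", i % 2, ages[i : i + 1]) for i in range(n)]
        accs = chance_run(samples, n_repeats=5, seed=2, k=5, cost_grid=(1.0,))
        assert abs(accs.mean() - 0.5) < 0.12
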