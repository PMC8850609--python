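import numpy as np
import pytest

from thermoprick.evaluation import (
    FoldPlan,
    accuracy_from_confusion,
    average_precision,
    confusion_and_accuracy,
    evaluate_scores,
    f1_optimal_threshold,
    make_patient_folds,
    roc_auc,
)


# --- independent oracles: exhaustive pair counting / threshold enumeration ---

def auc_by_pair_counting(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def ap_by_threshold_enumeration(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    order = np.argsort(-scores, kind="stable")
    labels, scores = labels[order], scores[order]
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestRocAuc:
    def test_perfect_and_inverted_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert roc_auc([1, 0], [0.4, 0.6]) == 0.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])

    def test_matches_pair_counting_oracle_exactly(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 13))
            labels = rng.integers(0, 2, n)
            if len(set(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert roc_auc(labels, scores) == pytest.approx(
                auc_by_pair_counting(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = rng.random(30)
        a = roc_auc(labels, scores)
        assert roc_auc(labels, np.exp(5 * scores)) == pytest.approx(a, abs=1e-12)


class TestAveragePrecision:
    def test_perfect_ranking_gives_one(self):
        assert average_precision([0, 1, 1], [0.1, 0.8, 0.9]) == 1.0

    def test_hand_enumerated_example(self):
        # precisions at recalls {0.5, 1.0} are {1, 2/3}: AP = 5/6
        assert average_precision([1, 0, 1], [0.9, 0.8, 0.7]) == \
            pytest.approx(5 / 6)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            average_precision([0, 0], [0.2, 0.8])

    def test_matches_threshold_enumeration_oracle_exactly(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 13))
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                continue
            scores = np.round(rng.random(n), 1)
            assert average_precision(labels, scores) == pytest.approx(
                ap_by_threshold_enumeration(labels, scores), abs=1e-12)

    def test_reversed_separable_scores_hit_brute_force_minimum(self):
        labels = np.array([1, 1, 0, 0, 0])
        scores = np.array([0.1, 0.2, 0.7, 0.8, 0.9])
        assert average_precision(labels, scores) == pytest.approx(
            ap_by_threshold_enumeration(labels, scores), abs=1e-12)


class TestF1Threshold:
    def test_scores_equal_labels_pick_candidate_nearest_half(self):
        t = f1_optimal_threshold([0, 1, 0, 1], [0.0, 1.0, 0.0, 1.0])
        assert t == pytest.approx(0.5)

    def test_three_regime_enumeration(self):
        # regimes: all positive F1=0.8 / top-2 F1=0.5 / top-1 F1=2/3
        t = f1_optimal_threshold([1, 0, 1], [0.9, 0.8, 0.7])
        assert t < 0.7
        _, acc = confusion_and_accuracy([1, 0, 1], [0.9, 0.8, 0.7], t)
        tp = 2
        assert 2 * tp / (2 * tp + 1 + 0) == pytest.approx(0.8)

    def test_duplicating_a_sample_keeps_the_threshold(self, rng):
        labels = [1, 0, 1, 0, 1]
        scores = [0.9, 0.6, 0.7, 0.2, 0.4]
        t1 = f1_optimal_threshold(labels, scores)
        t2 = f1_optimal_threshold(labels + [labels[0]], scores + [scores[0]])
        assert t1 == t2


class TestConfusionAndAccuracy:
    def test_counts_and_percentage(self):
        confusion, acc = confusion_and_accuracy(
            [1, 0, 1, 0, 0, 0, 1, 1], [0.9, 0.1, 0.2, 0.8, 0.3, 0.4, 0.7, 0.6],
            0.5)
        assert confusion.tolist() == [[3, 1], [1, 3]]
        assert acc == pytest.approx(75.0)

    def test_all_correct_is_hundred_percent(self):
        _, acc = confusion_and_accuracy([0, 1], [0.1, 0.9], 0.5)
        assert acc == 100.0

    def test_matrix_accuracy_consistent_with_direct(self, rng):
        labels = rng.integers(0, 2, 50)
        scores = rng.random(50)
        confusion, acc = confusion_and_accuracy(labels, scores, 0.5)
        assert confusion.sum() == 50
        assert accuracy_from_confusion(confusion) == pytest.approx(acc,
                                                                   abs=1e-9)

    def test_threshold_rule_is_greater_equal(self):
        confusion, _ = confusion_and_accuracy([1], [0.5], 0.5)
        assert confusion[1, 1] == 1  # tie predicted positive


class TestFoldPlans:
    def test_ten_patients_ten_folds_singletons(self):
        plan = make_patient_folds([f"p{i}" for i in range(10)], k=10, seed=0)
        assert all(len(test) == 1 for _, test in plan.folds)

    def test_loocv_fold_count_equals_patients(self):
        plan = make_patient_folds([f"p{i}" for i in range(100)], loocv=True)
        assert plan.k == 100 and len(plan.folds) == 100

    @pytest.mark.parametrize("k,n,seed", [(2, 5, 0), (3, 7, 1), (5, 20, 2),
                                          (10, 23, 3)])
    def test_disjointness_and_coverage(self, k, n, seed):
        ids = [f"p{i}" for i in range(n)]
        plan = make_patient_folds(ids, k=k, seed=seed)
        covered = []
        for train, test in plan.folds:
            assert not set(train) & set(test)
            assert sorted(train + test) == sorted(ids)
            covered.extend(test)
        assert sorted(covered) == sorted(ids)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            make_patient_folds(["a", "b"], k=3)
        with pytest.raises(ValueError):
            make_patient_folds(["a", "b", "c"], k=1)

    def test_overlapping_plan_rejected_by_invariant(self):
        with pytest.raises(ValueError):
            FoldPlan(folds=[(["a"], ["b"]), (["a"], ["b"])], k=2, seed=0)


class TestEvaluateScores:
    def test_report_is_internally_consistent(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        scores = np.clip(labels * 0.6 + rng.random(40) * 0.4, 0, 1)
        report = evaluate_scores(labels, scores)
        assert report.confusion.sum() == 40
        assert accuracy_from_confusion(report.confusion) == \
            pytest.approx(report.accuracy, abs=1e-9)
        assert 0 <= report.roc_auc <= 1
        assert 0 <= report.average_precision <= 1
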