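"""Patient-grouped cross-validation and the reported metrics.

Folding is over *patients*, never over sites: all sites of a patient share
interview attributes and forearm context, so site-level folds would leak
identity into the test set.  Per fold the classifier refits its
normalisation statistics on the training patients only.  Metrics follow
the usual definitions: ROC AUC (rank statistic, ties half-counted),
average precision (step-wise, non-interpolated), and accuracy at the
threshold maximising F1 on the pooled cross-validated scores (ties broken
toward 0.5; prediction rule is ``score >= threshold``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn import metrics as _skm

from .classifier import ReactionClassifier, Sample


@dataclass
class FoldPlan:
    folds: List[Tuple[List[str], List[str]]]  # (train_ids, test_ids)
    k: int
    seed: int

    def __post_init__(self) -> None:
        seen: set = set()
        for train, test in self.folds:
            overlap = set(train) & set(test)
            if overlap:
                raise ValueError(f"train/test overlap: {sorted(overlap)[:3]}")
            dup = seen & set(test)
            if dup:
                raise ValueError(f"patient in two test folds: {sorted(dup)[:3]}")
            seen |= set(test)


@dataclass
class EvalReport:
    roc_auc: float
    average_precision: float
    threshold: float
    accuracy: float            # percent
    confusion: np.ndarray      # 2x2, rows true (neg, pos), cols predicted
    n: int

    def as_dict(self) -> dict:
        return {
            "roc_auc": round(self.roc_auc, 4),
            "average_precision": round(self.average_precision, 4),
            "threshold": round(self.threshold, 4),
            "accuracy_pct": round(self.accuracy, 2),
            "confusion": self.confusion.astype(int).tolist(),
            "n": self.n,
        }


def make_patient_folds(patient_ids: Sequence[str], k: Optional[int] = None,
                       seed: int = 0, loocv: bool = False) -> FoldPlan:
    """Shuffle patients by seed and partition into k near-equal test groups.

    ``loocv=True`` (or ``k == n_patients``) gives leave-one-patient-out.
    """
    unique = sorted(set(map(str, patient_ids)))
    n = len(unique)
    if loocv:
        k = n
    if k is None or k < 2 or k > n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    rng = np.random.Generator(np.random.PCG64(seed))
    order = [unique[i] for i in rng.permutation(n)]
    groups = np.array_split(order, k)
    folds = [(sorted(set(order) - set(g)), sorted(g)) for g in groups]
    return FoldPlan(folds=folds, k=k, seed=seed)


def _check_both_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve (probability a random positive outranks a
    random negative; ties counted half)."""
    labels = np.asarray(labels)
    _check_both_classes(labels)
    return float(_skm.roc_auc_score(labels, np.asarray(scores, dtype=float)))

def average_precision(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Step-wise average precision: sum of (recall step) x precision over
    descending-score thresholds."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("average precision undefined without positives")
    return float(_skm.average_precision_score(labels,
                                              np.asarray(scores, dtype=float)))


def f1_optimal_threshold(labels: Sequence[int],
                         scores: Sequence[float]) -> float:
    """Threshold maximising F1 with the ``score >= t`` prediction rule.

    Candidates are midpoints between consecutive sorted unique scores plus
    the endpoints {0, 1}; among maximisers the one nearest 0.5 wins.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    _check_both_classes(labels)
    uniq = np.unique(scores)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    best_f1, best_t = -1.0, 0.5
    for t in candidates:
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        fn = np.sum(~pred & (labels == 1))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1 + 1e-12 or (abs(f1 - best_f1) <= 1e-12
                                    and abs(t - 0.5) < abs(best_t - 0.5)):
            best_f1, best_t = f1, float(t)
    return best_t


def confusion_and_accuracy(labels: Sequence[int], scores: Sequence[float],
                           threshold: float) -> Tuple[np.ndarray, float]:
    """2x2 confusion counts (rows true, cols predicted) and accuracy in %."""
    labels = np.asarray(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tp = int(np.sum(pred & (labels == 1)))
    confusion = np.array([[tn, fp], [fn, tp]])
    accuracy = 100.0 * (tn + tp) / max(confusion.sum(), 1)
    return confusion, accuracy


def accuracy_from_confusion(confusion: np.ndarray) -> float:
    """Accuracy (percent) from a 2x2 confusion matrix."""
    confusion = np.asarray(confusion)
    return 100.0 * float(np.trace(confusion)) / float(confusion.sum())


def evaluate_scores(labels: Sequence[int], scores: Sequence[float],
                    threshold: Optional[float] = None) -> EvalReport:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    t = f1_optimal_threshold(labels, scores) if threshold is None else threshold
    confusion, acc = confusion_and_accuracy(labels, scores, t)
    return EvalReport(roc_auc=roc_auc(labels, scores),
                      average_precision=average_precision(labels, scores),
                      threshold=t, accuracy=acc, confusion=confusion,
                      n=int(len(labels)))


def run_cross_validation(samples: Sequence[Sample], input_mode: str = "both",
                         k: int = 10, seed: int = 0, loocv: bool = False,
                         classifier_kwargs: Optional[dict] = None,
                         ) -> Tuple[EvalReport, List[EvalReport]]:
    """Patient-grouped k-fold CV; threshold selected on the pooled scores.

    Per fold a fresh :class:`ReactionClassifier` is fitted on the training
    patients (normalisation statistics included), then scores the test
    patients.  All test scores are pooled for the summary report; per-fold
    reports use the pooled threshold.
    """
    samples = list(samples)
    ids = [s.patient_id for s in samples]
    plan = make_patient_folds(ids, k=k, seed=seed, loocv=loocv)
    kwargs = dict(classifier_kwargs or {})
    kwargs.setdefault("seed", seed)
    pooled_scores = np.empty(len(samples))
    pooled_mask = np.zeros(len(samples), dtype=bool)
    fold_indices: List[np.ndarray] = []
    for train_ids, test_ids in plan.folds:
        train = [s for s in samples if s.patient_id in set(train_ids)]
        test_idx = np.array([i for i, s in enumerate(samples)
                             if s.patient_id in set(test_ids)])
        clf = ReactionClassifier(input_mode=input_mode, **kwargs)
        clf.fit(train)
        assert not (clf.norm_stats_.train_patient_ids & set(test_ids)), \
            "normalisation statistics leaked test patients"
        pooled_scores[test_idx] = clf.predict_proba([samples[i]
                                                     for i in test_idx])
        pooled_mask[test_idx] = True
        fold_indices.append(test_idx)
    assert pooled_mask.all(), "some samples were never scored"
    labels = np.array([s.label for s in samples])
    pooled = evaluate_scores(labels, pooled_scores)
    per_fold = []
    for idx in fold_indices:
        if len(np.unique(labels[idx])) < 2:
            continue
        per_fold.append(evaluate_scores(labels[idx], pooled_scores[idx],
                                        threshold=pooled.threshold))
    return pooled, per_fold


def run_ablation(samples: Sequence[Sample],
                 modes: Sequence[str] = ("both", "thermal_only", "visible_only"),
                 k: int = 10, seed: int = 0,
                 classifier_kwargs: Optional[dict] = None,
                 ) -> Dict[str, EvalReport]:
    """Input-spectra ablation grid: one pooled CV report per mode."""
    return {mode: run_cross_validation(samples, input_mode=mode, k=k,
                                       seed=seed,
                                       classifier_kwargs=classifier_kwargs)[0]
            for mode in modes}
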