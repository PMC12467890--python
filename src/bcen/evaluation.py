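"""Classification metrics, stratified cross-validation, structure-recovery
scoring and the two-sample test used for method comparison."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .types import BrainGraph, DirectedConnectome, GroundTruthNetwork

__all__ = [
    "ClassificationMetrics",
    "confusion_metrics",
    "CrossValidationResult",
    "kfold_cross_validate",
    "recovery_scores",
    "two_sample_ttest",
]

logger = logging.getLogger(__name__)


@dataclass
class ClassificationMetrics:
    """Binary-classification summary; rates are percentages in [0, 100].

    A ratio with a zero denominator (e.g. sensitivity with no positive
    samples) is reported as NaN with a logged warning, never silently as 0.
    """

    acc: float
    sen: float
    spe: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _ratio(num: int, denom: int, name: str) -> float:
    if denom == 0:
        logger.warning("%s undefined (zero denominator); reporting NaN", name)
        return float("nan")
    return 100.0 * num / denom


def confusion_metrics(y_true: Sequence, y_pred: Sequence,
                      positive_class=1) -> ClassificationMetrics:
    """Accuracy, sensitivity, specificity and F1 (as percentages) from the
    binary confusion table with the given positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    tp = int(np.sum(pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    return ClassificationMetrics(
        acc=_ratio(tp + tn, tp + tn + fp + fn, "accuracy"),
        sen=_ratio(tp, tp + fn, "sensitivity"),
        spe=_ratio(tn, tn + fp, "specificity"),
        f1=_ratio(2 * tp, 2 * tp + fp + fn, "F1"),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


@dataclass
class CrossValidationResult:
    """Per-fold metrics plus the pooled-confusion aggregate."""

    fold_metrics: list[ClassificationMetrics]
    pooled: ClassificationMetrics
    fold_assignment: np.ndarray   # test-fold index of each sample


def kfold_fold_assignment(labels: np.ndarray, k: int,
                          seed: int) -> np.ndarray:
    """Seeded stratified fold assignment: entry ``j`` is the test fold of
    sample ``j``."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)),
                                                   labels)):
        assignment[test_idx] = fold
    return assignment


def kfold_cross_validate(dataset: Sequence[BrainGraph],
                         model_factory: Callable[[], object],
                         k: int = 10, seed: int = 0,
                         positive_class: int = 1) -> CrossValidationResult:
    """Stratified k-fold cross-validation of a graph classifier.

    ``model_factory`` must return an object with ``fit(graphs)`` (labels
    taken from the graphs) and ``predict(graphs)``.  Each sample is tested
    exactly once; the headline metrics aggregate the pooled confusion counts
    over all folds.
    """
    n = len(dataset)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    if any(g.label is None for g in dataset):
        raise ValueError("every graph must carry a label")
    labels = np.array([g.label for g in dataset], dtype=int)
    assignment = kfold_fold_assignment(labels, k, seed)
    y_true_all = np.empty(n, dtype=int)
    y_pred_all = np.empty(n, dtype=int)
    fold_metrics = []
    for fold in range(k):
        test_mask = assignment == fold
        train = [dataset[j] for j in np.flatnonzero(~test_mask)]
        test = [dataset[j] for j in np.flatnonzero(test_mask)]
        model = model_factory()
        model.fit(train)
        preds = np.asarray(model.predict(test))
        y_true = labels[test_mask]
        y_true_all[test_mask] = y_true
        y_pred_all[test_mask] = preds
        fold_metrics.append(
            confusion_metrics(y_true, preds, positive_class=positive_class)
        )
    pooled = confusion_metrics(y_true_all, y_pred_all,
                               positive_class=positive_class)
    return CrossValidationResult(fold_metrics=fold_metrics, pooled=pooled,
                                 fold_assignment=assignment)


def recovery_scores(estimate: DirectedConnectome,
                    truth: GroundTruthNetwork) -> tuple[float, float]:
    """Ranking scores of an estimated network against the generating graph.

    Off-diagonal absolute estimate entries are treated as edge scores and
    the truth's nonzero pattern as binary labels; returns (AUROC, AUPRC)
    computed by rank statistics with ties averaged.
    """
    if estimate.v != truth.v:
        raise ValueError(
            f"dimension mismatch: estimate v={estimate.v}, truth v={truth.v}"
        )
    v = truth.v
    mask = ~np.eye(v, dtype=bool)
    scores = np.abs(estimate.weights[mask])
    labels = (truth.adjacency[mask] != 0).astype(int)
    if labels.min() == labels.max():
        raise ValueError(
            "truth must contain at least one edge and one non-edge"
        )
    return (float(roc_auc_score(labels, scores)),
            float(average_precision_score(labels, scores)))


def two_sample_ttest(a: Sequence[float],
                     b: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample must contain at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            # identical constants: no evidence of a difference
            return 0.0, 1.0
        raise ValueError("degenerate zero-variance samples with "
                         "different means")
    t_stat, p_val = stats.ttest_ind(a, b, equal_var=False)
    return float(t_stat), float(p_val)
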