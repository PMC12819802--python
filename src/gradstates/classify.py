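"""LOOCV linear-SVM classification of gradient features.

One subject is held out per fold; features are standardized on the
training fold only (no leakage), a linear maximum-margin classifier is
fitted, and the held-out decision score is recorded. Confusion counts
accumulate over the N folds; the ROC/AUC is built from the pooled held-out
scores with AUC computed by the rank (Mann-Whitney) formulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.svm import SVC


@dataclass
class ClassificationReport:
    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    auc: float | None
    folds: int = 0
    feature_ranking: list[tuple[str, float]] = field(default_factory=list)
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def _ratio(num: int, den: int) -> float | None:
    """Percent ratio; ``None`` (undefined), never 0, for a zero denominator."""
    return None if den == 0 else 100.0 * num / den


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formulation with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def classification_metrics(tp: int, fn: int, tn: int, fp: int,
                           scores: np.ndarray | None = None,
                           labels: np.ndarray | None = None
                           ) -> ClassificationReport:
    """Confusion-matrix metrics (percent) plus optional rank AUC.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/N, precision = TP/(TP+FP); any metric with a zero
    denominator is reported as undefined (``None``), not 0.
    """
    for name, v in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a nonnegative integer, got {v}")
    n = tp + fn + tn + fp
    auc = None
    if scores is not None and labels is not None:
        auc = rank_auc(scores, labels)
    return ClassificationReport(
        tp=tp, fn=fn, tn=tn, fp=fp,
        accuracy=_ratio(tp + tn, n),
        precision=_ratio(tp, tp + fp),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        auc=auc,
    )


def loocv_classify(features: np.ndarray, labels, C: float = 1.0,
                   feature_names: list[str] | None = None
                   ) -> ClassificationReport:
    """Leave-one-out cross-validated linear SVM.

    ``labels`` must have exactly two levels; the second (sorted order) is
    the positive class. Constant features are dropped with a warning.
    Returns the fold-accumulated confusion matrix, percent metrics, rank
    AUC over pooled held-out decision scores, and features ranked by mean
    absolute weight across folds.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if n < 6:
        raise ValueError("LOOCV needs at least 6 subjects")
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 classes, got {list(levels)}")
    y = (labels == levels[1]).astype(int)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("each class needs at least 2 subjects for LOOCV")

    keep = x.std(axis=0) > 1e-14
    if not keep.all():
        dropped = np.where(~keep)[0].tolist()
        warnings.warn(f"dropping constant feature(s) {dropped}")
        x = x[:, keep]
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(x.shape[1])]
    else:
        feature_names = [nm for nm, k in zip(feature_names, keep) if k]

    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    weights = np.zeros((n, x.shape[1]))
    for i in range(n):
        tr = np.arange(n) != i
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"a class is absent from the training fold {i}")
        mu, sd = x[tr].mean(axis=0), x[tr].std(axis=0)
        sd = np.where(sd < 1e-14, 1.0, sd)
        clf = SVC(kernel="linear", C=C)
        clf.fit((x[tr] - mu) / sd, y[tr])
        z = (x[i] - mu) / sd
        scores[i] = float(clf.decision_function(z[None, :])[0])
        preds[i] = int(clf.predict(z[None, :])[0])
        weights[i] = clf.coef_[0]

    tp = int(((preds == 1) & (y == 1)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    report = classification_metrics(tp, fn, tn, fp, scores=scores, labels=y)
    mean_w = np.abs(weights).mean(axis=0)
    order = np.argsort(mean_w)[::-1]
    report.feature_ranking = [(feature_names[j], float(mean_w[j])) for j in order]
    report.folds = n
    report.scores = scores
    report.labels = y
    return report


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(FPR, TPR) pairs over all score thresholds, for plotting/export."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    order = np.argsort(-scores)
    tps = np.cumsum(y[order])
    fps = np.cumsum(~y[order])
    tpr = np.concatenate([[0], tps / max(y.sum(), 1)])
    fpr = np.concatenate([[0], fps / max((~y).sum(), 1)])
    return np.column_stack([fpr, tpr])
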