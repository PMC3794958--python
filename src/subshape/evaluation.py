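"""Cross-validated evaluation: confusion metrics, ROC/AUC, incremental
learning curves, and permutation significance testing.

Conventions: the amyloid-positive class is the "positive" class of every
metric (sensitivity = true-positive rate among PiB(+), specificity =
true-negative rate among PiB(−)). Folds are stratified so the 23/45 class
imbalance is preserved in every partition, decision scores are pooled
across test folds for the ROC, and the permutation test permutes only the
labels used for training — held-out subjects are always scored against
their true labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .classifier import NEGATIVE, POSITIVE, PCALDAClassifier


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("negative confusion count")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n


def confusion_metrics(predictions, labels):
    """(sensitivity, specificity, accuracy, ConfusionMatrix); the positive
    class is PiB(+) = 1."""
    p = np.asarray(predictions).ravel().astype(int)
    t = np.asarray(labels).ravel().astype(int)
    if len(p) == 0 or len(p) != len(t):
        raise ValueError("predictions and labels must be non-empty, same length")
    cm = ConfusionMatrix(
        tp=int(np.sum((p == POSITIVE) & (t == POSITIVE))),
        fn=int(np.sum((p == NEGATIVE) & (t == POSITIVE))),
        tn=int(np.sum((p == NEGATIVE) & (t == NEGATIVE))),
        fp=int(np.sum((p == POSITIVE) & (t == NEGATIVE))),
    )
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("both classes must be present in the labels")
    return cm.sensitivity, cm.specificity, cm.accuracy, cm


def counts_from_rates(sensitivity: float, specificity: float,
                      n_pos: int, n_neg: int) -> ConfusionMatrix:
    """Recover integer confusion counts from printed sensitivity/specificity
    and the class sizes; errors if the rates are not consistent with
    integer counts at the printed precision."""
    tp = sensitivity * n_pos
    tn = specificity * n_neg
    tpi, tni = round(tp), round(tn)
    if abs(tp - tpi) > 0.01 * n_pos or abs(tn - tni) > 0.01 * n_neg:
        raise ValueError(
            f"rates ({sensitivity}, {specificity}) inconsistent with class "
            f"sizes ({n_pos}, {n_neg})"
        )
    return ConfusionMatrix(tp=tpi, fn=n_pos - tpi, tn=tni, fp=n_neg - tni)


def stratified_folds(labels, k: int, seed: int) -> np.ndarray:
    """Fold assignment (0..k-1 per subject) preserving class proportions;
    within each class, fold sizes differ by at most one."""
    y = np.asarray(labels).ravel().astype(int)
    rng = np.random.default_rng(seed)
    assign = np.full(len(y), -1, int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % k
    for fold in range(k):
        train_y = y[assign != fold]
        if len(np.unique(train_y)) < 2:
            raise ValueError(
                f"training partition for fold {fold} lacks a class; "
                "use fewer folds"
            )
    return assign


@dataclass
class CVResult:
    fold_assignment: np.ndarray
    predictions: np.ndarray  # out-of-fold labels
    scores: np.ndarray  # out-of-fold decision scores
    labels: np.ndarray  # true labels
    confusion: ConfusionMatrix = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    accuracy: float = field(init=False)
    roc: tuple = field(init=False)
    auc: float = field(init=False)

    def __post_init__(self) -> None:
        self.sensitivity, self.specificity, self.accuracy, self.confusion = \
            confusion_metrics(self.predictions, self.labels)
        self.roc, self.auc = roc_auc(self.scores, self.labels)


def run_cv(
    X,
    labels,
    k: int = 10,
    seed: int = 0,
    variance_fraction: float = 0.70,
    train_labels=None,
) -> CVResult:
    """Stratified k-fold cross-validation of the PCA+LDA classifier.

    ``train_labels``, if given, replaces the labels seen during training
    (the permutation-test hook); evaluation always uses the true ``labels``.
    k = n gives leave-one-out.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(labels).ravel().astype(int)
    y_train = y if train_labels is None else \
        np.asarray(train_labels).ravel().astype(int)
    assign = stratified_folds(y_train, k, seed)
    preds = np.empty(len(y), int)
    scores = np.empty(len(y), float)
    for fold in range(k):
        test = assign == fold
        if not test.any():
            continue
        clf = PCALDAClassifier(variance_fraction)
        clf.fit(X[~test], y_train[~test])
        s = clf.decision_function(X[test])
        scores[test] = s
        preds[test] = np.where(s >= 0, POSITIVE, NEGATIVE)
    return CVResult(assign, preds, scores, y)


def roc_auc(scores, labels):
    """ROC points and AUC; AUC is the Mann–Whitney fraction of correctly
    ordered positive/negative pairs (ties count one half)."""
    s = np.asarray(scores, float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    n_pos = int(np.sum(y == POSITIVE))
    n_neg = int(np.sum(y == NEGATIVE))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for ROC")
    r = rankdata(s)
    auc = (r[y == POSITIVE].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # ROC by sweeping thresholds at the unique scores
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    tps = np.cumsum(ys == POSITIVE)
    fps = np.cumsum(ys == NEGATIVE)
    # keep last point of each tied-score run
    keep = np.r_[np.diff(s[order]) != 0, True]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    return (fpr, tpr), float(auc)


@dataclass
class LearningCurve:
    sizes: np.ndarray  # training-set sizes (multiples of batch size)
    mean_accuracy: np.ndarray
    n_orders: int
    per_order_accuracy: np.ndarray  # (n_orders, len(sizes))


def learning_curve(
    X_train,
    y_train,
    X_test,
    y_test,
    n_orders: int = 500,
    batch_size: int = 10,
    seed: int = 0,
    variance_fraction: float = 0.70,
) -> LearningCurve:
    """Incremental-learning accuracy vs number of training subjects.

    For each of ``n_orders`` random presentation orders of the training
    subjects, batches of ``batch_size`` are absorbed via ``partial_fit``
    and the full test set is scored after every batch; accuracies are then
    averaged over orders. Because incremental updating is exact, the final
    point coincides with batch training on the whole set.
    """
    if batch_size < 1 or n_orders < 1:
        raise ValueError("batch_size and n_orders must be >= 1")
    X_train = np.atleast_2d(np.asarray(X_train, float))
    y_train = np.asarray(y_train).ravel().astype(int)
    n = len(y_train)
    sizes = list(range(batch_size, n, batch_size)) + [n]
    rng = np.random.default_rng(seed)
    acc = np.full((n_orders, len(sizes)), np.nan)
    y_test = np.asarray(y_test).ravel().astype(int)
    for o in range(n_orders):
        order = rng.permutation(n)
        clf = PCALDAClassifier(variance_fraction)
        start = 0
        for j, size in enumerate(sizes):
            idx = order[start:size]
            start = size
            clf.partial_fit(X_train[idx], y_train[idx])
            if not hasattr(clf, "lda_"):
                # not enough of each class yet: accuracy undefined at this
                # size for this order
                continue
            preds = clf.predict(X_test)
            acc[o, j] = float(np.mean(preds == y_test))
    with np.errstate(invalid="ignore"):
        mean_acc = np.nanmean(acc, axis=0)
    return LearningCurve(np.asarray(sizes), mean_acc, n_orders, acc)


@dataclass
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    n_permutations: int
    seed: int


def permutation_test(
    X,
    labels,
    n_perm: int = 10000,
    seed: int = 0,
    k: int = 10,
    variance_fraction: float = 0.70,
) -> PermutationResult:
    """Significance of the cross-validated accuracy by label permutation.

    Each permutation shuffles the labels used for *training* within the
    same k-fold CV procedure; held-out subjects are scored against their
    true labels, and the pooled CV accuracy is the null statistic. The
    p-value uses the add-one estimator
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(labels).ravel().astype(int)
    rng = np.random.default_rng(seed)
    observed = run_cv(X, y, k=k, seed=seed, variance_fraction=variance_fraction).accuracy
    null = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        res = run_cv(
            X, y, k=k, seed=int(rng.integers(2**31)),
            variance_fraction=variance_fraction, train_labels=yp,
        )
        null[i] = res.accuracy
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return PermutationResult(observed, null, p, n_perm, seed)
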