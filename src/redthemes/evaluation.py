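"""Splits, confusion matrices, precision/recall/F-measure, accuracy and MRR.

Conventions are fixed throughout the package: confusion-matrix rows are
actual classes and columns predicted classes; the F-measure is the harmonic
mean of precision and recall; "weighted average" weights each class by its
support (true-instance count), which makes weighted recall identical to
accuracy; and the Mean Reciprocal Rank is

    MRR = (1/|P|) * sum_i 1 / rank_i

over the set P of classified posts, where rank_i is the 1-based position of
post i's true class once classes are sorted by descending predicted
probability (ties broken by ascending class index). A correct prediction has
rank 1, so MRR >= accuracy always, with equality iff every correct class is
ranked first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import LabeledCorpus


@dataclass
class ConfusionMatrix:
    """K x K counts; entry (i, j) = posts of actual class i predicted as j."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match the class list")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f_measure: float
    support: int


@dataclass
class MetricsReport:
    """Per-class and aggregate metrics of one classifier on one test set."""

    per_class: dict[str, ClassMetrics]
    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f_measure: float
    mrr: float | None = None
    warnings: list[str] = field(default_factory=list)


def split_dataset(
    corpus: LabeledCorpus, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledCorpus, LabeledCorpus]:
    """Simple seeded random split; reuse the SAME split for every classifier."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = len(corpus)
    if n < 2:
        raise ValueError("need at least two posts to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    tr, te = perm[:n_train], perm[n_train:]
    pick = lambda idx: LabeledCorpus(
        [corpus.posts[i] for i in idx], [corpus.labels[i] for i in idx]
    )
    return pick(tr), pick(te)


def confusion(
    truth: Sequence[str], predicted: Sequence[str], class_order: Sequence[str]
) -> ConfusionMatrix:
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    classes = tuple(class_order)
    lookup = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        if t not in lookup or p not in lookup:
            raise ValueError(f"label outside class order: {t!r} / {p!r}")
        counts[lookup[t], lookup[p]] += 1
    return ConfusionMatrix(counts, classes)


def _safe_div(num: float, den: float, warnings: list[str], what: str) -> float:
    if den == 0:
        warnings.append(f"zero denominator for {what}; reported as 0")
        return 0.0
    return num / den


def binary_metrics(cm: ConfusionMatrix, positive_class: str | None = None) -> MetricsReport:
    """Precision/recall/F/accuracy of a 2x2 matrix for a designated positive class.

    By default the second class is positive (for the mental-vs-control task:
    class order (control, mental), positive = mental).
    """
    if cm.counts.shape != (2, 2):
        raise ValueError("binary_metrics needs a 2x2 confusion matrix")
    pos = 1 if positive_class is None else cm.classes.index(positive_class)
    neg = 1 - pos
    c = cm.counts
    tp, fn = int(c[pos, pos]), int(c[pos, neg])
    fp, tn = int(c[neg, pos]), int(c[neg, neg])
    warnings: list[str] = []
    precision = _safe_div(tp, tp + fp, warnings, "precision")
    recall = _safe_div(tp, tp + fn, warnings, "recall")
    fm = _safe_div(2 * precision * recall, precision + recall, warnings, "F-measure")
    accuracy = _safe_div(tp + tn, cm.total, warnings, "accuracy")
    neg_warn: list[str] = []
    neg_precision = _safe_div(tn, tn + fn, neg_warn, "neg precision")
    neg_recall = _safe_div(tn, tn + fp, neg_warn, "neg recall")
    neg_fm = _safe_div(2 * neg_precision * neg_recall, neg_precision + neg_recall,
                       neg_warn, "neg F-measure")
    per_class = {
        cm.classes[pos]: ClassMetrics(precision, recall, fm, tp + fn),
        cm.classes[neg]: ClassMetrics(neg_precision, neg_recall, neg_fm, tn + fp),
    }
    support = np.array([per_class[c_].support for c_ in cm.classes], dtype=float)
    weights = support / support.sum() if support.sum() else support
    wp = float(sum(w * per_class[c_].precision for w, c_ in zip(weights, cm.classes)))
    wr = float(sum(w * per_class[c_].recall for w, c_ in zip(weights, cm.classes)))
    wf = float(sum(w * per_class[c_].f_measure for w, c_ in zip(weights, cm.classes)))
    return MetricsReport(per_class, accuracy, wp, wr, wf, warnings=warnings)


def multiclass_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class (column precision, row recall, F) and support-weighted averages."""
    c = cm.counts
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    warnings: list[str] = []
    per_class: dict[str, ClassMetrics] = {}
    support = cm.support().astype(float)
    for i, name in enumerate(cm.classes):
        tp = float(c[i, i])
        precision = _safe_div(tp, float(c[:, i].sum()), warnings, f"precision[{name}]")
        recall = _safe_div(tp, float(c[i, :].sum()), warnings, f"recall[{name}]")
        fm = _safe_div(2 * precision * recall, precision + recall, warnings, f"FM[{name}]")
        per_class[name] = ClassMetrics(precision, recall, fm, int(support[i]))
    weights = support / support.sum()
    wp = float(sum(w * per_class[n].precision for w, n in zip(weights, cm.classes)))
    wr = float(sum(w * per_class[n].recall for w, n in zip(weights, cm.classes)))
    wf = float(sum(w * per_class[n].f_measure for w, n in zip(weights, cm.classes)))
    accuracy = float(np.trace(c)) / cm.total
    return MetricsReport(per_class, accuracy, wp, wr, wf, warnings=warnings)


def rank_of_truth(probabilities: np.ndarray, truth_index: np.ndarray) -> np.ndarray:
    """1-based rank of each post's true class in its probability ordering.

    Ties are broken by ascending class index, consistently with argmax
    prediction (the lowest-index class among a tied maximum is both the
    predicted class and rank 1).
    """
    probs = np.asarray(probabilities, dtype=float)
    truth_index = np.asarray(truth_index, dtype=int)
    if probs.ndim != 2:
        raise ValueError("probabilities must be 2-D (posts x classes)")
    if (truth_index < 0).any() or (truth_index >= probs.shape[1]).any():
        raise ValueError("truth class absent from ranking")
    n = len(truth_index)
    p_true = probs[np.arange(n), truth_index]
    higher = (probs > p_true[:, None]).sum(axis=1)
    tied_before = (
        (probs == p_true[:, None]) & (np.arange(probs.shape[1])[None, :] < truth_index[:, None])
    ).sum(axis=1)
    return (higher + tied_before + 1).astype(np.int64)


def mean_reciprocal_rank(probabilities: np.ndarray, truth_index: np.ndarray) -> float:
    """MRR = mean of 1/rank_i over the classified posts."""
    ranks = rank_of_truth(probabilities, truth_index)
    return float((1.0 / ranks).mean())


def ablate_class(corpus: LabeledCorpus, class_name: str) -> LabeledCorpus:
    """Remove every post of one class; at least two classes must remain.

    Removing a class with no posts returns the corpus unchanged. The caller
    re-derives the class order from the remaining labels and reruns the
    split/train/evaluate stages untouched.
    """
    remaining = {l for l in corpus.labels if l is not None and l != class_name}
    if class_name in set(corpus.labels) and len(remaining) < 2:
        raise ValueError("ablation would leave fewer than two classes")
    keep = [i for i, l in enumerate(corpus.labels) if l != class_name]
    return LabeledCorpus([corpus.posts[i] for i in keep], [corpus.labels[i] for i in keep])
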