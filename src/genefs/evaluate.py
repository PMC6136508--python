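"""Final classification on a selected gene subset: metrics, ROC, AUC, and
nested-subset size selection from a ranked list.

The ROC is built from continuous SVM decision values with thresholds swept
over the unique scores; AUC is the trapezoidal area, which equals the
Mann-Whitney pair-counting estimate with ties counted half.  The positive
class is +1 (cancer) by convention.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from ._rand import child_seed
from .io_expr import ExpressionMatrix
from .svm_core import cv_accuracy, train_svm
from .svm_rfe import RankedList

__all__ = ["EvalReport", "metrics_from_counts", "evaluate_subset",
           "select_best_subset", "plot_roc"]


@dataclasses.dataclass
class EvalReport:
    """Confusion counts, derived metrics, and the ROC for one gene subset."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f_score: float
    auc: float
    roc_points: np.ndarray  # (k, 2) array of (FPR, TPR), (0,0) .. (1,1)
    subset: list[str]

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for name in ("tp", "fp", "fn", "tn"):
                fh.write(f"{name}\t{getattr(self, name)}\n")
            for name in ("accuracy", "precision", "recall", "f_score", "auc"):
                fh.write(f"{name}\t{getattr(self, name)!r}\n")
            fh.write("subset\t" + ",".join(self.subset) + "\n")
        return path

    def roc_to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("fpr\ttpr\n")
            for fpr, tpr in self.roc_points:
                fh.write(f"{fpr!r}\t{tpr!r}\n")
        return path


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) from confusion counts; empty
    denominators yield 0.0."""
    n = tp + fp + fn + tn
    accuracy = (tp + tn) / n if n else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return accuracy, precision, recall, f


def evaluate_subset(
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    subset: Sequence[str],
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: float | None = None,
) -> EvalReport:
    """Train on the subset, score the test set, and report the metric suite."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    tr = train.subset_genes(subset)   # raises if a gene is missing
    te = test.subset_genes(subset)
    if gamma is None and kernel == "rbf":
        gamma = 1.0 / len(subset)
    model = train_svm(tr, kernel=kernel, C=C, gamma=gamma)
    scores = model.decision_function(te.values)
    pred = np.where(scores >= 0.0, 1, -1)
    y = te.labels
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == -1)))
    fn = int(np.sum((pred == -1) & (y == 1)))
    tn = int(np.sum((pred == -1) & (y == -1)))
    accuracy, precision, recall, f = metrics_from_counts(tp, fp, fn, tn)
    if len(np.unique(y)) < 2:
        raise ValueError("test set must contain both classes for ROC/AUC")
    fpr, tpr, _ = roc_curve(y, scores, pos_label=1, drop_intermediate=False)
    auc_value = float(_trapezoid_auc(fpr, tpr))
    return EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=accuracy, precision=precision, recall=recall, f_score=f,
        auc=auc_value,
        roc_points=np.column_stack([fpr, tpr]),
        subset=subset,
    )


def select_best_subset(
    ranked: RankedList | Sequence[str],
    train: ExpressionMatrix,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: float | None = None,
    folds: int = 5,
    seed: int = 0,
    max_size: int | None = None,
) -> tuple[list[str], float]:
    """Sweep nested top-k subsets by training-set CV accuracy.

    Returns the smallest k achieving the maximum accuracy (the
    fewer-features tie rule) together with that accuracy.  ``ranked`` may be
    a :class:`RankedList` or any importance-ordered gene sequence (most
    important first).
    """
    order = ranked.by_rank() if isinstance(ranked, RankedList) else list(ranked)
    if not order:
        raise ValueError("ranking is empty")
    missing = [g for g in order if g not in set(train.gene_ids)]
    if missing:
        raise ValueError(f"ranking covers gene(s) absent from train: {missing[:5]}")
    limit = len(order) if max_size is None else min(max_size, len(order))
    cv_seed = child_seed(seed, "subset-cv")
    best_k, best_acc = 1, -np.inf
    for k in range(1, limit + 1):
        sub = train.subset_genes(order[:k])
        g = gamma if gamma is not None else 1.0 / k
        acc = cv_accuracy(
            sub, kernel=kernel, C=C, gamma=g if kernel == "rbf" else None,
            folds=folds, seed=cv_seed,
        )
        if acc > best_acc:  # strict: smallest k wins ties
            best_acc, best_k = acc, k
    return order[:best_k], float(best_acc)


def plot_roc(
    reports: dict[str, EvalReport], path: str | Path, title: str = "ROC"
) -> Path:
    """Draw one or more ROC curves on a single axis (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, rep in reports.items():
        ax.plot(rep.roc_points[:, 0], rep.roc_points[:, 1],
                label=f"{name} (AUC={rep.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
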