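"""Soft-margin SVM contract and cross-validated accuracy.

The dual quadratic program is solved by scikit-learn's libsvm binding; this
module fixes the interface the rest of the package relies on: the trained
model exposes its dual coefficients alpha_i * y_i, support vectors and bias,
the decision function f(x) = sum_i alpha_i y_i K(x_i, x) + b, and the
(pseudo-)weight vector omega = sum_i alpha_i y_i x_i used for feature
ranking.  Cross-validation uses a documented seed-to-fold assignment rule
so that fold membership depends only on (sample_ids, labels, folds, seed),
never on row order.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .io_expr import ExpressionMatrix

__all__ = ["SvmModel", "train_svm", "linear_weight_vector", "cv_accuracy",
           "stratified_fold_indices"]


@dataclasses.dataclass
class SvmModel:
    """A trained binary SVM with its dual solution exposed.

    ``dual_coefficients[i]`` is alpha_i * y_i for the i-th support vector,
    bounded in [-C, C]; their sum is 0 up to solver tolerance.
    """

    kernel: str
    C: float
    gamma: float | None
    dual_coefficients: np.ndarray
    support_vectors: np.ndarray
    bias: float
    feature_ids: list[str]
    _svc: SVC = dataclasses.field(repr=False, default=None)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """f(x) = sum_i alpha_i y_i K(x_i, x) + b; sign classifies, magnitude ranks."""
        return self._svc.decision_function(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0.0, 1, -1)

    def kernel_matrix(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        B = np.asarray(B, dtype=float)
        if self.kernel == "linear":
            return A @ B.T
        sq = (
            np.sum(A**2, axis=1)[:, None]
            + np.sum(B**2, axis=1)[None, :]
            - 2.0 * (A @ B.T)
        )
        return np.exp(-self.gamma * np.maximum(sq, 0.0))


def train_svm(
    train: ExpressionMatrix,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: float | None = None,
) -> SvmModel:
    """Fit a binary soft-margin SVM on the full training matrix.

    ``gamma`` is required for the RBF kernel and ignored for the linear
    kernel.  Labels must contain both classes.
    """
    if kernel not in ("linear", "rbf"):
        raise ValueError(f"unsupported kernel {kernel!r}")
    if C <= 0:
        raise ValueError("C must be positive")
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training labels contain a single class")
    if kernel == "rbf":
        if gamma is None or gamma <= 0:
            raise ValueError("rbf kernel requires gamma > 0")
        svc = SVC(kernel="rbf", C=C, gamma=gamma)
    else:
        svc = SVC(kernel="linear", C=C)
        gamma = None
    svc.fit(train.values, train.labels)
    return SvmModel(
        kernel=kernel,
        C=C,
        gamma=gamma,
        dual_coefficients=svc.dual_coef_[0].copy(),
        support_vectors=svc.support_vectors_.copy(),
        bias=float(svc.intercept_[0]),
        feature_ids=list(train.gene_ids),
        _svc=svc,
    )


def linear_weight_vector(model: SvmModel) -> np.ndarray:
    """omega = sum_i alpha_i y_i x_i over support vectors.

    For the linear kernel this is the exact primal weight vector.  For the
    RBF kernel it is the pseudo-weight obtained by applying the same sum in
    input space, which is what the elimination criterion ranks on.
    """
    return model.dual_coefficients @ model.support_vectors


def stratified_fold_indices(
    labels: np.ndarray,
    sample_ids: Sequence[str],
    folds: int,
    seed: int,
) -> list[np.ndarray]:
    """Assign samples to folds by a rule invariant to row order.

    Within each class, samples are ordered by sample_id, shuffled by the
    seeded generator, and dealt round-robin to the folds.  ``folds`` equal
    to the sample count yields leave-one-out (stratification is vacuous).
    """
    labels = np.asarray(labels)
    n = len(labels)
    if folds < 2:
        raise ValueError("folds must be at least 2")
    if folds == n:
        order = np.argsort(np.asarray(sample_ids, dtype=object), kind="stable")
        return [np.array([i]) for i in order]
    fold_members: list[list[int]] = [[] for _ in range(folds)]
    rng = np.random.default_rng(seed)
    for cls in sorted(np.unique(labels).tolist()):
        cls_idx = np.flatnonzero(labels == cls)
        if len(cls_idx) < folds:
            raise ValueError(
                f"class {cls} has {len(cls_idx)} samples, fewer than {folds} folds"
            )
        by_id = cls_idx[np.argsort([sample_ids[i] for i in cls_idx], kind="stable")]
        shuffled = by_id[rng.permutation(len(by_id))]
        for pos, i in enumerate(shuffled):
            fold_members[pos % folds].append(int(i))
    return [np.array(sorted(m), dtype=int) for m in fold_members]


def _cv_accuracy_arrays(
    X: np.ndarray,
    y: np.ndarray,
    sample_ids: Sequence[str],
    kernel: str,
    C: float,
    gamma: float | None,
    folds: int,
    seed: int,
) -> float:
    fold_sets = stratified_fold_indices(y, sample_ids, folds, seed)
    accs = []
    all_idx = np.arange(len(y))
    for test_idx in fold_sets:
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        train_idx = all_idx[mask]
        if kernel == "rbf":
            svc = SVC(kernel="rbf", C=C, gamma=gamma)
        else:
            svc = SVC(kernel="linear", C=C)
        svc.fit(X[train_idx], y[train_idx])
        accs.append(float(np.mean(svc.predict(X[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


def cv_accuracy(
    expr: ExpressionMatrix,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: float | None = None,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean held-out accuracy over stratified folds (unweighted average).

    Deterministic under a fixed seed; the fold assignment depends only on
    sample identifiers and labels, not on row order.
    """
    if kernel == "rbf" and (gamma is None or gamma <= 0):
        raise ValueError("rbf kernel requires gamma > 0")
    return _cv_accuracy_arrays(
        expr.values, expr.labels, expr.sample_ids, kernel, C, gamma, folds, seed
    )
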