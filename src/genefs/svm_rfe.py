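"""SVM recursive feature elimination with optional per-stage (C, gamma) tuning.

At each iteration the SVM is retrained on the surviving genes, each gene k
is scored by c_k = omega_k^2 with omega the (pseudo-)weight vector, and the
lowest-scoring gene is removed; prepending removed genes yields a total
ranking with rank 1 = last survivor = most important.  When an optimizer is
active, (C, gamma) are re-chosen by maximizing cross-validated accuracy on
the surviving genes, either every iteration or on a cheaper cadence.

Under the RBF kernel the weight vector is not defined in input space; the
default criterion applies c_k = omega_k^2 to the pseudo-weight
omega = sum_i alpha_i y_i x_i.  A kernel-space alternative — the change in
the margin term alpha^T diag(y) K diag(y) alpha when feature k is dropped —
is available as ``criterion="kernel"``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from ._rand import child_seed
from .io_expr import ExpressionMatrix
from .param_opt import (
    OptimizerResult,
    ParamPair,
    SearchSpace,
    ga_search,
    grid_search,
    pso_search,
)
from .svm_core import SvmModel, _cv_accuracy_arrays, linear_weight_vector, train_svm

__all__ = ["RankedList", "IterationRecord", "ranking_scores", "rfe_rank"]


@dataclasses.dataclass
class IterationRecord:
    """Bookkeeping for one elimination step."""

    n_surviving: int
    removed_gene: str
    score: float
    params: ParamPair | None


@dataclasses.dataclass
class RankedList:
    """Total elimination order over genes.

    ``elimination_order`` runs from first-removed (least important) to last
    survivor; ``rank`` maps gene -> 1..D with 1 the most important.
    """

    elimination_order: list[str]
    rank: dict[str, int]
    per_iteration: list[IterationRecord]

    def by_rank(self) -> list[str]:
        """Genes from rank 1 (most important) downward."""
        return list(reversed(self.elimination_order))

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("rank\tgene_id\telimination_iteration\tscore\tC\tgamma\n")
            for it, rec in enumerate(self.per_iteration, start=1):
                c = repr(rec.params.C) if rec.params else ""
                g = repr(rec.params.gamma) if rec.params else ""
                fh.write(
                    f"{self.rank[rec.removed_gene]}\t{rec.removed_gene}\t"
                    f"{it}\t{rec.score!r}\t{c}\t{g}\n"
                )
        return path


def ranking_scores(model: SvmModel, criterion: str = "weight") -> np.ndarray:
    """Per-feature elimination scores for a trained model.

    ``"weight"``: c_k = omega_k^2 from the (pseudo-)weight vector — exact
    for the linear kernel, the pragmatic input-space reading for RBF.
    ``"kernel"``: c_k = |W2 - W2^{(-k)}| where W2 = alpha^T diag(y) K diag(y)
    alpha, recomputed with feature k removed from the kernel.
    """
    if criterion == "weight":
        return linear_weight_vector(model) ** 2
    if criterion != "kernel":
        raise ValueError(f"unknown criterion {criterion!r}")
    a = model.dual_coefficients  # alpha_i * y_i
    sv = model.support_vectors
    K = model.kernel_matrix(sv, sv)
    scores = np.empty(sv.shape[1])
    for k in range(sv.shape[1]):
        d = sv[:, k][:, None] - sv[:, k][None, :]
        if model.kernel == "rbf":
            K_minus = K * np.exp(model.gamma * d**2)
        else:
            K_minus = K - np.outer(sv[:, k], sv[:, k])
        scores[k] = abs(float(a @ K @ a) - float(a @ K_minus @ a))
    return scores


_OPTIMIZERS = {"grid", "pso", "ga"}


def _optimize_params(
    optimizer: str,
    X: np.ndarray,
    y: np.ndarray,
    sample_ids: Sequence[str],
    kernel: str,
    space: SearchSpace,
    cv_folds: int,
    cv_seed: int,
    opt_seed: int,
    optimizer_kwargs: dict,
) -> OptimizerResult:
    def fitness(pair: ParamPair) -> float:
        return _cv_accuracy_arrays(
            X, y, sample_ids, kernel, pair.C,
            pair.gamma if kernel == "rbf" else None,
            cv_folds, cv_seed,
        )

    if optimizer == "grid":
        return grid_search(fitness, space)
    if optimizer == "pso":
        return pso_search(fitness, space, seed=opt_seed, **optimizer_kwargs)
    return ga_search(fitness, space, seed=opt_seed, **optimizer_kwargs)


def rfe_rank(
    train: ExpressionMatrix,
    optimizer: str = "none",
    kernel: str = "rbf",
    fixed_params: ParamPair | None = None,
    reoptimize_every: int = 1,
    seed: int = 0,
    criterion: str = "weight",
    space: SearchSpace | None = None,
    cv_folds: int = 5,
    optimizer_kwargs: dict | None = None,
) -> RankedList:
    """Recursively eliminate genes until none survive, ranking all of them.

    Parameters
    ----------
    optimizer
        ``"none"`` uses ``fixed_params`` throughout; ``"grid"``, ``"pso"``
        or ``"ga"`` re-optimize (C, gamma) by maximizing stratified
        cross-validated accuracy on the surviving genes.  With a linear
        kernel only C affects the fitness, so the search effectively tunes
        C alone.
    reoptimize_every
        Cadence in elimination iterations between optimizer runs (1 = every
        iteration); the latest optimum is reused in between.
    fixed_params
        (C, gamma) used when no optimizer is active.  Defaults to C = 1 and
        gamma = 1 / D with D the initial gene count.
    """
    if train.n_genes < 1:
        raise ValueError("at least one gene is required")
    if optimizer not in _OPTIMIZERS and optimizer != "none":
        raise ValueError(f"unknown optimizer {optimizer!r}")
    if reoptimize_every < 1:
        raise ValueError("reoptimize_every must be >= 1")
    counts = train.class_counts()
    if len(counts) < 2 or min(counts.values()) < 2:
        raise ValueError("each class needs at least 2 training samples")
    space = space or SearchSpace()
    optimizer_kwargs = dict(optimizer_kwargs or {})

    if fixed_params is None:
        fixed_params = ParamPair(C=1.0, gamma=1.0 / train.n_genes)
    params = fixed_params

    surviving = list(range(train.n_genes))  # original column indices, ascending
    elimination_order: list[str] = []
    per_iteration: list[IterationRecord] = []
    cv_seed = child_seed(seed, "rfe-cv")

    t = 0
    while surviving:
        X = train.values[:, surviving]
        ids = [train.gene_ids[j] for j in surviving]
        if optimizer != "none" and t % reoptimize_every == 0 and len(surviving) > 0:
            result = _optimize_params(
                optimizer, X, train.labels, train.sample_ids, kernel,
                space, cv_folds, cv_seed, child_seed(seed, "rfe-opt", t),
                optimizer_kwargs,
            )
            params = result.best
        sub = ExpressionMatrix(X, ids, list(train.sample_ids), train.labels)
        model = train_svm(
            sub, kernel=kernel, C=params.C,
            gamma=params.gamma if kernel == "rbf" else None,
        )
        scores = ranking_scores(model, criterion=criterion)
        # argmin returns the first minimum; surviving is kept in ascending
        # original column order, so ties fall to the lowest column index.
        k = int(np.argmin(scores))
        removed = ids[k]
        per_iteration.append(
            IterationRecord(
                n_surviving=len(surviving),
                removed_gene=removed,
                score=float(scores[k]),
                params=params if (optimizer != "none" or fixed_params) else None,
            )
        )
        elimination_order.append(removed)
        del surviving[k]
        t += 1

    D = len(elimination_order)
    rank = {g: D - i for i, g in enumerate(elimination_order)}
    return RankedList(
        elimination_order=elimination_order, rank=rank, per_iteration=per_iteration
    )
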