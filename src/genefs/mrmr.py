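"""Minimum-redundancy maximum-relevance gene ranking and candidate-set sizing.

Expression values are z-scored per gene and coded to three levels
(-1 / 0 / +1 at one standard deviation), mutual information is estimated by
the plug-in formula on the empirical joint distribution (bits), and genes
are picked greedily: the first maximizes relevance MI(gene, label), each
later pick maximizes relevance minus mean redundancy against the already
selected set (the MID scheme; MIQ, the quotient form, is available behind a
flag).  The candidate-set size n* is read off the cross-validation error
curve e_k over nested prefixes: within the band of k whose error is within
a tolerance of the minimum, the smallest k attaining the minimum wins.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from sklearn.metrics import mutual_info_score

from ._rand import child_seed
from .io_expr import ExpressionMatrix
from .svm_core import cv_accuracy

__all__ = [
    "MrmrRanking",
    "CandidateSetResult",
    "discretize",
    "mutual_information",
    "mrmr_rank",
    "candidate_size_from_errors",
    "select_candidate_size",
]

_LN2 = float(np.log(2.0))


@dataclasses.dataclass
class MrmrRanking:
    """Greedy selection order (first = most relevant) with per-step scores."""

    selection_order: list[str]
    scores: list[float]

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("k\tgene_id\tscore\n")
            for k, (g, s) in enumerate(zip(self.selection_order, self.scores), 1):
                fh.write(f"{k}\t{g}\t{s!r}\n")
        return path


@dataclasses.dataclass
class CandidateSetResult:
    """CV error curve over nested prefixes and the chosen size n*.

    ``omega`` is the set of prefix sizes whose error is within ``tolerance``
    of the minimum; ``n_star`` is the smallest member of omega attaining the
    minimum error ``e_star``.
    """

    errors_by_k: np.ndarray
    omega: list[int]
    e_star: float
    n_star: int


def discretize(expr: ExpressionMatrix) -> np.ndarray:
    """Three-level coding of z-scored expression: +1 above one sd, -1 below
    minus one sd, 0 otherwise (strict inequalities).  Zero-variance genes
    code to all zeros."""
    X = expr.values
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    codes = np.zeros(X.shape, dtype=int)
    ok = sd > 0
    z = np.zeros_like(X)
    z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    codes[z > 1.0] = 1
    codes[z < -1.0] = -1
    codes[:, ~ok] = 0
    return codes


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information of two discrete vectors, in bits.

    MI(x, x) equals the empirical entropy H(x)."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    return float(mutual_info_score(x, y)) / _LN2


def mrmr_rank(
    expr: ExpressionMatrix, n: int | None = None, scheme: str = "MID"
) -> MrmrRanking:
    """Greedy mRMR selection of ``n`` genes (all genes by default).

    MID score: MI(gene, label) - mean_s MI(gene, s) over the selected set S.
    MIQ score: MI(gene, label) / (mean_s MI(gene, s) + 1e-12).
    Ties fall to the lowest column index.
    """
    if scheme not in ("MID", "MIQ"):
        raise ValueError(f"unknown scheme {scheme!r}")
    p = expr.n_genes
    n = p if n is None else int(n)
    if not 1 <= n <= p:
        raise ValueError("n must lie in 1..gene count")
    codes = discretize(expr)
    y = expr.labels
    relevance = np.array([mutual_information(codes[:, j], y) for j in range(p)])

    selected: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(p)
    candidates = np.ones(p, dtype=bool)
    for step in range(n):
        if step == 0:
            score = relevance.copy()
        else:
            mean_red = red_sum / len(selected)
            if scheme == "MID":
                score = relevance - mean_red
            else:
                score = relevance / (mean_red + 1e-12)
        score[~candidates] = -np.inf
        j = int(np.argmax(score))  # first max = lowest column index on ties
        selected.append(j)
        scores.append(float(score[j]))
        candidates[j] = False
        mi_new = np.array(
            [
                mutual_information(codes[:, k], codes[:, j]) if candidates[k] else 0.0
                for k in range(p)
            ]
        )
        red_sum += mi_new
    return MrmrRanking(
        selection_order=[expr.gene_ids[j] for j in selected], scores=scores
    )


def candidate_size_from_errors(
    errors: np.ndarray, tolerance: float
) -> CandidateSetResult:
    """Apply the omega/n* rule to a precomputed error curve e_1..e_n."""
    errors = np.asarray(errors, dtype=float)
    n = len(errors)
    if n == 0:
        raise ValueError("error curve is empty")
    e_min = float(errors.min())
    omega = [k for k in range(1, n + 1) if errors[k - 1] <= e_min + tolerance]
    e_star = min(float(errors[k - 1]) for k in omega)
    n_star = min(k for k in omega if errors[k - 1] == e_star)
    return CandidateSetResult(
        errors_by_k=errors, omega=omega, e_star=e_star, n_star=n_star
    )


def select_candidate_size(
    ranking: MrmrRanking,
    expr: ExpressionMatrix,
    folds: int = 5,
    tolerance: float = 0.01,
    seed: int = 0,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: float | None = None,
) -> CandidateSetResult:
    """Choose the candidate-set size from the CV error curve over prefixes.

    e_k = 1 - cv_accuracy on the first k selected genes; omega is the band
    of k with e_k within ``tolerance`` of min_j e_j; n* is the smallest k in
    omega attaining the minimum."""
    if not ranking.selection_order:
        raise ValueError("ranking is empty")
    n = len(ranking.selection_order)
    errors = np.empty(n)
    cv_seed = child_seed(seed, "mrmr-cv")
    for k in range(1, n + 1):
        sub = expr.subset_genes(ranking.selection_order[:k])
        g = gamma if gamma is not None else 1.0 / k
        errors[k - 1] = 1.0 - cv_accuracy(
            sub, kernel=kernel, C=C, gamma=g if kernel == "rbf" else None,
            folds=folds, seed=cv_seed,
        )
    return candidate_size_from_errors(errors, tolerance)
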