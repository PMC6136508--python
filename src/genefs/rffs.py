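"""Random-forest backward feature elimination (RFFS) and its grid-tuned variant.

Backward search ordered by forest variable importance: each outer iteration
runs stratified k-fold cross-validation, averages the per-fold accuracies
(TLMean) and the per-fold impurity-decrease importances, records the best
TLMean seen so far (TGMax) with its importance-sorted gene set (FGSort),
and removes the least-important gene.  Elimination stops when two genes
remain.  Ties on the best accuracy update — the condition is
TGMax <= TLMean — so a later, smaller gene set with equal mean accuracy
replaces an earlier one.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from ._rand import child_seed
from .io_expr import ExpressionMatrix
from .param_opt import RfParamPair, rf_grid_search
from .svm_core import stratified_fold_indices

__all__ = ["RffsResult", "RffsIteration", "rf_importance", "rffs_rank", "rffs_gs"]


@dataclasses.dataclass
class RffsIteration:
    n_surviving: int
    surviving_genes: list[str]
    importances: np.ndarray          # aligned with surviving_genes
    tl_mean: float
    tl_max: float
    removed_gene: str
    importance_order: list[str]      # descending importance


@dataclasses.dataclass
class RffsResult:
    """Best mean CV accuracy (TGMax) and its importance-sorted gene set."""

    tg_max: float
    fg_sort: list[str]
    trace: list[RffsIteration]
    params: RfParamPair

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("iteration\tn_surviving\ttl_mean\ttl_max\tremoved_gene\n")
            for t, rec in enumerate(self.trace, start=1):
                fh.write(
                    f"{t}\t{rec.n_surviving}\t{rec.tl_mean!r}\t{rec.tl_max!r}\t"
                    f"{rec.removed_gene}\n"
                )
            fh.write("# FGSort: " + ",".join(self.fg_sort) + "\n")
        return path


def default_rf_params(n_genes: int) -> RfParamPair:
    """100 trees, sqrt(p) features per split (rounded up)."""
    return RfParamPair(
        max_features=max(1, math.ceil(math.sqrt(n_genes))), n_estimators=100
    )


def _fit_forest(
    X: np.ndarray, y: np.ndarray, params: RfParamPair, seed: int
) -> RandomForestClassifier:
    rf = RandomForestClassifier(
        n_estimators=params.n_estimators,
        max_features=min(params.max_features, X.shape[1]),
        random_state=seed,
    )
    rf.fit(X, y)
    return rf


def rf_importance(
    expr: ExpressionMatrix, params: RfParamPair | None = None, seed: int = 0
) -> np.ndarray:
    """Impurity-decrease importance per gene from a seeded forest."""
    counts = expr.class_counts()
    if len(counts) < 2 or min(counts.values()) < 2:
        raise ValueError("each class needs at least 2 samples")
    params = params or default_rf_params(expr.n_genes)
    rf = _fit_forest(expr.values, expr.labels, params, seed)
    return rf.feature_importances_.copy()


def _importance_order(genes: list[str], importances: np.ndarray) -> list[str]:
    # Descending importance; ties keep the lower original position first.
    order = np.argsort(-importances, kind="stable")
    return [genes[i] for i in order]


def rffs_rank(
    expr: ExpressionMatrix,
    params: RfParamPair | None = None,
    folds: int = 10,
    seed: int = 0,
) -> RffsResult:
    """Backward elimination tracking the best mean k-fold accuracy.

    Each outer iteration: deal the samples into stratified folds, train a
    forest per fold, record fold accuracies, average the fold importances,
    update (TGMax, FGSort) when the mean accuracy is at least the best so
    far, then drop the gene with the smallest averaged importance (lowest
    column index on ties).  Runs until two genes survive.
    """
    if expr.n_genes < 3:
        raise ValueError("at least 3 genes are required for elimination")
    counts = expr.class_counts()
    if len(counts) < 2 or min(counts.values()) < folds:
        raise ValueError(f"each class needs at least {folds} samples for {folds} folds")
    params = params or default_rf_params(expr.n_genes)

    surviving = list(range(expr.n_genes))
    tg_max = 0.0
    fg_sort: list[str] = []
    trace: list[RffsIteration] = []

    for t in range(expr.n_genes - 2):
        X = expr.values[:, surviving]
        genes = [expr.gene_ids[j] for j in surviving]
        fold_sets = stratified_fold_indices(
            expr.labels, expr.sample_ids, folds, child_seed(seed, "rffs-folds", t)
        )
        accs = np.empty(folds)
        imp_sum = np.zeros(len(surviving))
        all_idx = np.arange(expr.n_samples)
        for i, test_idx in enumerate(fold_sets):
            mask = np.ones(expr.n_samples, dtype=bool)
            mask[test_idx] = False
            rf = _fit_forest(
                X[all_idx[mask]], expr.labels[all_idx[mask]], params,
                child_seed(seed, "rffs-rf", t, i),
            )
            accs[i] = float(np.mean(rf.predict(X[test_idx]) == expr.labels[test_idx]))
            imp_sum += rf.feature_importances_
        tl_mean = float(np.mean(accs))
        tl_max = float(np.max(accs))
        importances = imp_sum / folds
        order = _importance_order(genes, importances)
        if tg_max <= tl_mean:  # ties update, keeping the later/smaller set
            tg_max = tl_mean
            fg_sort = order
        k = int(np.argmin(importances))  # first min = lowest column index
        trace.append(
            RffsIteration(
                n_surviving=len(surviving),
                surviving_genes=genes,
                importances=importances,
                tl_mean=tl_mean,
                tl_max=tl_max,
                removed_gene=genes[k],
                importance_order=order,
            )
        )
        del surviving[k]

    return RffsResult(tg_max=tg_max, fg_sort=fg_sort, trace=trace, params=params)


def default_rf_grids(n_genes: int) -> tuple[list[int], list[int]]:
    mf = sorted({
        max(1, math.ceil(math.sqrt(n_genes))),
        max(1, math.ceil(n_genes / 3)),
        max(1, math.ceil(n_genes / 5)),
    })
    return mf, [50, 100, 200, 500]


def rffs_gs(
    expr: ExpressionMatrix,
    max_features_grid: Sequence[int] | None = None,
    n_estimators_grid: Sequence[int] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> RffsResult:
    """Grid-tune (max_features, n_estimators) by CV accuracy on the full
    gene set, then run :func:`rffs_rank` with the chosen pair."""
    mf_default, ne_default = default_rf_grids(expr.n_genes)
    max_features_grid = list(max_features_grid or mf_default)
    n_estimators_grid = list(n_estimators_grid or ne_default)
    fold_sets = stratified_fold_indices(
        expr.labels, expr.sample_ids, folds, child_seed(seed, "rffs-gs-folds")
    )
    all_idx = np.arange(expr.n_samples)

    def fitness(pair: RfParamPair) -> float:
        accs = []
        for i, test_idx in enumerate(fold_sets):
            mask = np.ones(expr.n_samples, dtype=bool)
            mask[test_idx] = False
            rf = _fit_forest(
                expr.values[all_idx[mask]], expr.labels[all_idx[mask]], pair,
                child_seed(seed, "rffs-gs-rf", pair.n_estimators, pair.max_features, i),
            )
            accs.append(
                float(np.mean(rf.predict(expr.values[test_idx]) == expr.labels[test_idx]))
            )
        return float(np.mean(accs))

    best = rf_grid_search(fitness, max_features_grid, n_estimators_grid)
    return rffs_rank(expr, params=best.best, folds=folds, seed=seed)
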