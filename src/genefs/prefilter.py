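"""Per-gene differential-expression testing and FDR-based screening.

A two-sided Welch (unequal-variance) t-test gives a p-value per gene;
Benjamini-Hochberg step-up adjustment converts these to q-values, and
genes with q below a strict threshold are retained as candidates for the
downstream selectors.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_expr import ExpressionMatrix

__all__ = [
    "DiffExprResult",
    "welch_t_pvalues",
    "bh_qvalues",
    "differential_expression",
    "filter_by_q",
]


@dataclasses.dataclass
class DiffExprResult:
    """Per-gene p-values and (optionally) FDR-adjusted q-values."""

    gene_ids: list[str]
    p_values: np.ndarray
    q_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        if len(self.gene_ids) != len(self.p_values):
            raise ValueError("gene_ids and p_values length mismatch")
        if self.q_values is not None:
            self.q_values = np.asarray(self.q_values, dtype=float)
            if len(self.q_values) != len(self.gene_ids):
                raise ValueError("gene_ids and q_values length mismatch")

    def to_tsv(self, path: str | Path) -> Path:
        """Export (gene_id, p, q) sorted by ascending q (p if q absent)."""
        path = Path(path)
        q = self.q_values if self.q_values is not None else self.p_values
        order = np.argsort(q, kind="stable")
        with open(path, "w") as fh:
            fh.write("gene_id\tp_value\tq_value\n")
            for i in order:
                qv = "" if self.q_values is None else repr(float(self.q_values[i]))
                fh.write(f"{self.gene_ids[i]}\t{self.p_values[i]!r}\t{qv}\n")
        return path


def welch_t_pvalues(expr: ExpressionMatrix) -> DiffExprResult:
    """Two-sided Welch t-test p-value per gene between the two classes.

    A gene constant and identical in both groups carries no evidence and
    is assigned p = 1.0; a gene constant within each group but with
    different group values is maximally significant (p = 0.0).
    """
    pos = expr.values[expr.labels == 1]
    neg = expr.values[expr.labels == -1]
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise ValueError("each class needs at least 2 samples for a t-test")
    with np.errstate(all="ignore"):
        result = stats.ttest_ind(pos, neg, axis=0, equal_var=False)
        p = np.asarray(result.pvalue, dtype=float)
    # Zero variance in both groups leaves the statistic 0/0; resolve by the
    # group means: identical means carry no signal, distinct means full signal.
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        mean_gap = np.abs(pos.mean(axis=0) - neg.mean(axis=0))
        p[degenerate] = np.where(np.isclose(mean_gap[degenerate], 0.0), 1.0, 0.0)
    return DiffExprResult(list(expr.gene_ids), p)


def bh_qvalues(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order.

    For sorted p(1) <= ... <= p(m), q(i) = min_{j >= i} min(1, p(j) * m / j).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(expr: ExpressionMatrix) -> DiffExprResult:
    """Welch t-test plus BH adjustment in one call."""
    de = welch_t_pvalues(expr)
    de.q_values = bh_qvalues(de.p_values)
    return de


def filter_by_q(
    expr: ExpressionMatrix, de: DiffExprResult, threshold: float
) -> ExpressionMatrix:
    """Retain exactly the genes with q < threshold (strict), order preserved."""
    if de.q_values is None:
        raise ValueError("DiffExprResult has no q-values; run bh_qvalues first")
    lookup = dict(zip(de.gene_ids, de.q_values))
    missing = [g for g in expr.gene_ids if g not in lookup]
    if missing:
        raise ValueError(f"differential result lacks gene(s): {missing[:5]}")
    keep = [g for g in expr.gene_ids if lookup[g] < threshold]
    if not keep:
        raise ValueError(
            f"no gene passes q < {threshold}; raise the threshold to keep candidates"
        )
    return expr.subset_genes(keep)
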