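"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from genefs import ExpressionMatrix


def make_expr(values, labels, gene_prefix="G", sample_prefix="S") -> ExpressionMatrix:
    """Quick ExpressionMatrix from raw arrays with generated identifiers."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ExpressionMatrix(
        values,
        [f"{gene_prefix}{j+1}" for j in range(p)],
        [f"{sample_prefix}{i+1}" for i in range(n)],
        np.asarray(labels, dtype=int),
    )


@pytest.fixture
def two_class_gaussian():
    """40 samples x 12 genes; first 3 genes shifted by 2 sd in class +1."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(40, 12))
    labels = np.array([-1] * 20 + [1] * 20)
    X[20:, :3] += 2.0
    return make_expr(X, labels)


# ---------------------------------------------------------------------------
# Independent oracles (used by both module and acceptance tests).

def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Min-over-suffix enumeration of the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(1.0, p[order[j]] * m / (j + 1)) for j in range(i, m)
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


def mi_oracle_bits(x, y) -> float:
    """Plug-in mutual information from the explicit joint table, bits."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x)
    mi = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            pxy = np.mean((x == xv) & (y == yv))
            if pxy > 0:
                px = np.mean(x == xv)
                py = np.mean(y == yv)
                mi += pxy * np.log2(pxy / (px * py))
    return mi


def auc_pair_counting(y, scores) -> float:
    """Mann-Whitney estimate: P(score_pos > score_neg) + 0.5 P(tie)."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == -1]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
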