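"""Synthetic two-class expression matrices with known ground truth.

The generator emulates the structure of a two-class transcriptomic study:
a block of informative genes whose class means differ by ``delta`` standard
deviations, a block of redundant genes that are noisy copies of informative
ones (round-robin sources), and pure-noise genes.  A Gaussian mode mimics
normalized microarray intensities; a negative-binomial mode mimics RNA-seq
counts with the class effect applied on the log-mean scale.  Gene positions
are shuffled so column order carries no information.  Everything is
deterministic under the spec's seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .io_expr import ExpressionMatrix, write_expression

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate"]

_NB_BASE_MEAN = 100.0  # baseline count mean in negative-binomial mode


@dataclasses.dataclass
class SyntheticSpec:
    """Study design for one simulated data set.

    Defaults describe a small balanced two-class cohort (30 samples per
    class) with 100 genes of which 5 are informative at a one-standard-
    deviation shift of 2 and 5 are redundant copies — a size at which every
    selector in the package separates signal from noise while remaining
    cheap to run repeatedly.
    """

    n_per_class: int = 30
    p: int = 100
    k_informative: int = 5
    delta: float = 2.0
    k_redundant: int = 5
    redundancy_noise: float = 0.1
    mode: str = "gaussian"
    nb_dispersion: float = 0.5
    seed: int = 0
    n_negative: int | None = None  # override to emulate class imbalance

    def __post_init__(self) -> None:
        if self.k_informative + self.k_redundant > self.p:
            raise ValueError("k_informative + k_redundant must not exceed p")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.k_redundant > 0 and self.k_informative == 0:
            raise ValueError("redundant genes need at least one informative source")
        if self.mode not in ("gaussian", "negative-binomial"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_per_class < 1 or self.p < 1:
            raise ValueError("n_per_class and p must be positive")


@dataclasses.dataclass
class SyntheticTruth:
    """Disjoint partition of the generated genes by role."""

    informative_ids: list[str]
    redundant_ids: list[str]
    noise_ids: list[str]

    def all_ids(self) -> set[str]:
        return set(self.informative_ids) | set(self.redundant_ids) | set(self.noise_ids)


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float,
               size: tuple[int, ...]) -> np.ndarray:
    # Gamma-Poisson mixture: var = mean + dispersion * mean^2.
    if dispersion <= 0:
        return rng.poisson(mean, size=size).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion, size=size)
    return rng.poisson(lam).astype(float)


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one data set; class +1 carries the mean shift."""
    rng = np.random.default_rng(spec.seed)
    n_pos = spec.n_per_class
    n_neg = spec.n_negative if spec.n_negative is not None else spec.n_per_class
    n = n_pos + n_neg
    labels = np.concatenate([np.full(n_neg, -1), np.full(n_pos, 1)])

    k_inf, k_red = spec.k_informative, spec.k_redundant
    k_noise = spec.p - k_inf - k_red
    pos_rows = labels == 1

    if spec.mode == "gaussian":
        X = rng.normal(0.0, 1.0, size=(n, spec.p))
        X[np.ix_(pos_rows, np.arange(k_inf))] += spec.delta
        for r in range(k_red):
            src = r % k_inf
            X[:, k_inf + r] = X[:, src] + rng.normal(
                0.0, spec.redundancy_noise, size=n
            )
    else:
        mu_neg = _NB_BASE_MEAN
        mu_pos = _NB_BASE_MEAN * float(np.exp(spec.delta))
        X = np.empty((n, spec.p))
        for j in range(spec.p):
            if j < k_inf:
                X[~pos_rows, j] = _nb_counts(
                    rng, mu_neg, spec.nb_dispersion, (n_neg,)
                )
                X[pos_rows, j] = _nb_counts(
                    rng, mu_pos, spec.nb_dispersion, (n_pos,)
                )
            elif j < k_inf + k_red:
                src = (j - k_inf) % k_inf
                # Noisy copy on the log scale, rounded back to counts.
                factor = np.exp(rng.normal(0.0, spec.redundancy_noise, size=n))
                X[:, j] = np.round(X[:, src] * factor)
            else:
                X[:, j] = _nb_counts(rng, mu_neg, spec.nb_dispersion, (n,))

    width = max(4, len(str(spec.p)))
    base_ids = [f"G{j + 1:0{width}d}" for j in range(spec.p)]
    perm = rng.permutation(spec.p)
    X = X[:, perm]
    gene_ids = [base_ids[j] for j in perm]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    truth = SyntheticTruth(
        informative_ids=[base_ids[j] for j in range(k_inf)],
        redundant_ids=[base_ids[j] for j in range(k_inf, k_inf + k_red)],
        noise_ids=[base_ids[j] for j in range(k_inf + k_red, spec.p)],
    )
    expr = ExpressionMatrix(X, gene_ids, sample_ids, labels)
    return expr, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\trole\n")
        for g in truth.informative_ids:
            fh.write(f"{g}\tinformative\n")
        for g in truth.redundant_ids:
            fh.write(f"{g}\tredundant\n")
        for g in truth.noise_ids:
            fh.write(f"{g}\tnoise\n")
    return path


def write_dataset(
    spec: SyntheticSpec, outdir: str | Path
) -> tuple[Path, Path]:
    """Generate and write the matrix (with labels) and the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, truth = generate(spec)
    matrix_path = write_expression(expr, outdir / "expression.tsv")
    truth_path = write_truth(truth, outdir / "truth.tsv")
    return matrix_path, truth_path
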