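"""Expression-matrix container, delimited-text I/O and stratified splitting.

The canonical in-memory orientation is samples x genes.  Files may be
stored either way; genes-by-samples input is transposed on read.  Labels
are mapped to {-1, +1} at load time, with +1 the positive (cancer) class.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_expression", "write_expression", "stratified_split"]

_DELIMITERS = {".tsv": "\t", ".txt": "\t", ".csv": ","}


@dataclasses.dataclass
class ExpressionMatrix:
    """Two-class expression data: real matrix plus identifiers and labels.

    Attributes
    ----------
    values
        ``(n_samples, n_genes)`` float array, expression units as given
        (no transform is applied by the package).
    gene_ids, sample_ids
        Ordered unique identifiers for columns and rows respectively.
    labels
        Per-sample class in ``{-1, +1}``; ``+1`` is the positive class.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("sample_ids/labels length must equal the row count")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length must equal the column count")
        if len(set(self.gene_ids)) != p:
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing or non-finite value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be -1 or +1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([pos[g] for g in gene_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"gene {e.args[0]!r} not present in the matrix") from None

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given genes, in the given order."""
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(
            self.values[:, idx], [self.gene_ids[i] for i in idx],
            list(self.sample_ids), self.labels.copy(),
        )

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[idx], list(self.gene_ids),
            [self.sample_ids[i] for i in idx], self.labels[idx],
        )


def _detect_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return _DELIMITERS.get(path.suffix.lower(), "\t")


def _map_labels(raw: pd.Series, positive_label: str | None) -> np.ndarray:
    raw_str = raw.astype(str).str.strip()
    uniq = sorted(raw_str.unique())
    if len(uniq) != 2:
        raise ValueError(
            f"labels must take exactly two distinct values, got {uniq}"
        )
    if positive_label is not None:
        pos = str(positive_label)
        if pos not in uniq:
            raise ValueError(f"positive label {pos!r} not among observed labels {uniq}")
    elif set(uniq) == {"-1", "1"} or set(uniq) == {"-1", "+1"}:
        pos = "1" if "1" in uniq else "+1"
    else:
        # Lexicographically later raw label is taken as the positive class.
        pos = uniq[1]
    return np.where(raw_str == pos, 1, -1)


def read_expression(
    path: str | Path,
    orientation: str = "samples-by-genes",
    label_source: str | Path | None = None,
    delimiter: str | None = None,
    positive_label: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression table with a header row of identifiers.

    Parameters
    ----------
    orientation
        ``"samples-by-genes"`` (rows are samples) or ``"genes-by-samples"``
        (rows are genes; the matrix is transposed to canonical form).
    label_source
        Either the name of a label column inside a samples-by-genes table,
        or the path of a separate two-column (sample_id, label) file.
    delimiter
        Overrides the extension-based default (TSV for ``.tsv``/``.txt``,
        comma for ``.csv``).
    positive_label
        Raw label to map to +1; defaults to the lexicographically later of
        the two observed values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if orientation not in ("samples-by-genes", "genes-by-samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _detect_delimiter(path, delimiter)

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    header_ids = header[1:]
    dupes = {h for h in header_ids if header_ids.count(h) > 1}
    if dupes:
        kind = "gene" if orientation == "samples-by-genes" else "sample"
        raise ValueError(f"duplicate {kind} identifier(s) in header: {sorted(dupes)}")

    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        kind = "sample" if orientation == "samples-by-genes" else "gene"
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate {kind} identifier(s): {dup}")

    label_file: Path | None = None
    labels_raw: pd.Series | None = None
    if label_source is not None:
        if isinstance(label_source, Path) or (
            isinstance(label_source, str)
            and label_source not in df.columns
            and Path(label_source).exists()
        ):
            label_file = Path(label_source)
        elif orientation == "samples-by-genes" and str(label_source) in df.columns:
            labels_raw = df.pop(str(label_source))
        else:
            raise ValueError(
                f"label source {label_source!r} is neither a column of the table "
                "nor an existing file"
            )

    if orientation == "genes-by-samples":
        df = df.T

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].to_numpy()
        for i, cell in enumerate(raw):
            try:
                # float() round-trips repr output bit-exactly, unlike the
                # fast parser pandas applies during numeric coercion.
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"empty or non-numeric value at sample {df.index[i]!r}, "
                    f"gene {col!r}"
                ) from None
            if np.isnan(values[i, j]) and (cell is None or str(cell) == "nan"):
                raise ValueError(
                    f"empty or non-numeric value at sample {df.index[i]!r}, "
                    f"gene {col!r}"
                )

    sample_ids = [str(s) for s in df.index]
    gene_ids = [str(g) for g in df.columns]

    if label_file is not None:
        lsep = _detect_delimiter(label_file, delimiter)
        lab = pd.read_csv(label_file, sep=lsep, index_col=0, dtype=str)
        lab.index = lab.index.astype(str)
        missing = [s for s in sample_ids if s not in lab.index]
        if missing:
            raise ValueError(f"label file lacks sample(s): {missing[:5]}")
        labels_raw = lab.iloc[:, 0].reindex(sample_ids)
    if labels_raw is None:
        raise ValueError("no label source given: pass a label column name or file")

    labels = _map_labels(labels_raw, positive_label)
    return ExpressionMatrix(values, gene_ids, sample_ids, labels)


def write_expression(
    expr: ExpressionMatrix,
    path: str | Path,
    delimiter: str | None = None,
    label_column: str = "label",
) -> Path:
    """Write a samples-by-genes table with the labels as the first column.

    Values are written with full ``repr`` precision so that a subsequent
    :func:`read_expression` round-trips bit-exactly.
    """
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    with open(path, "w") as fh:
        fh.write(sep.join(["sample_id", label_column] + expr.gene_ids) + "\n")
        for i, sid in enumerate(expr.sample_ids):
            row = [sid, str(int(expr.labels[i]))]
            row += [repr(float(v)) for v in expr.values[i]]
            fh.write(sep.join(row) + "\n")
    return path


def stratified_split(
    expr: ExpressionMatrix, test_fraction: float, seed: int
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split samples into train/test preserving class proportions.

    Per class, ``round(class_count * test_fraction)`` samples go to the
    test set, chosen uniformly at random; the split is deterministic under
    a fixed seed and both halves keep the original sample order.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    counts = expr.class_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present to split")
    for cls, c in counts.items():
        if c < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in sorted(counts):
        cls_idx = np.flatnonzero(expr.labels == cls)
        n_test = int(round(len(cls_idx) * test_fraction))
        perm = rng.permutation(len(cls_idx))
        test_idx.extend(cls_idx[perm[:n_test]].tolist())
    test_set = set(test_idx)
    train_idx = [i for i in range(expr.n_samples) if i not in test_set]
    return expr.subset_samples(train_idx), expr.subset_samples(sorted(test_idx))
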