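"""Expression-matrix and label handling: IO, gene harmonization, splits, folds.

Conventions
-----------
Expression tables are delimited text (TSV/CSV) with one header row and one id
column, holding log2(x+1)-scale normalized counts.  The in-memory orientation
is always samples x genes; transposition happens only in the reader/writer.
Labels travel as two-column TSV (sample_id, class).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ExpressionMatrix",
    "LabeledDataset",
    "SplitResult",
    "AlignmentResult",
    "read_expression_table",
    "write_expression_table",
    "read_labels",
    "write_labels",
    "align_features",
    "stratified_split",
    "kfold_indices",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValueError(f"duplicate {what} id(s): {sorted(set(dups))}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """A samples x genes matrix of log2(x+1)-scale expression values."""

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains missing/non-finite entries")
        if (values < 0).any():
            raise ValueError("log2(x+1)-scale expression values must be >= 0")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.gene_ids)
        )

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[idx], self.gene_ids, tuple(self.sample_ids[i] for i in idx)
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: j for j, g in enumerate(self.gene_ids)}
        cols = [pos[g] for g in genes]
        return ExpressionMatrix(self.values[:, cols], tuple(genes), self.sample_ids)


@dataclass(frozen=True)
class LabeledDataset:
    """Expression matrix plus one class label per sample."""

    matrix: ExpressionMatrix
    labels: tuple[str, ...]
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(y) for y in self.labels))
        object.__setattr__(self, "class_names", tuple(str(c) for c in self.class_names))
        if len(self.labels) != self.matrix.n_samples:
            raise ValueError("need exactly one label per sample")
        _check_unique(self.class_names, "class")
        alphabet = set(self.class_names)
        unknown = sorted(set(self.labels) - alphabet)
        if unknown:
            raise ValueError(f"labels not in class alphabet: {unknown}")
        present = set(self.labels)
        if len(present) < 2:
            raise ValueError("a labeled dataset needs >= 2 classes with samples")

    @property
    def n_samples(self) -> int:
        return self.matrix.n_samples

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def label_indices(self) -> np.ndarray:
        """Labels encoded as indices into ``class_names`` order."""
        pos = {c: i for i, c in enumerate(self.class_names)}
        return np.array([pos[y] for y in self.labels], dtype=int)

    def class_counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in self.class_names}

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            self.matrix.subset_samples(idx),
            tuple(self.labels[i] for i in idx),
            self.class_names,
        )

    def restrict_genes(self, genes: Sequence[str]) -> "LabeledDataset":
        return LabeledDataset(self.matrix.subset_genes(genes), self.labels, self.class_names)


@dataclass(frozen=True)
class SplitResult:
    train: LabeledDataset
    test: LabeledDataset
    seed: int
    train_fraction: float


@dataclass(frozen=True)
class AlignmentResult:
    """align_features output: harmonized matrix plus the dropped genes."""

    matrix: ExpressionMatrix
    missing_genes: tuple[str, ...] = field(default_factory=tuple)


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(
    path: str | Path,
    orientation: str = "samples_by_genes",
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression table into samples x genes orientation.

    ``orientation`` declares how the *file* is laid out; the returned matrix
    is always samples x genes.  Row/column ids are preserved verbatim.
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty expression table: {path}")

    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep), None)
    if header is None or len(header) < 2:
        raise ValueError(f"expression table {path} lacks a usable header row")
    col_ids = [c.strip() for c in header[1:]]
    col_what = "gene" if orientation == "samples_by_genes" else "sample"
    row_what = "sample" if orientation == "samples_by_genes" else "gene"
    _check_unique(col_ids, col_what)

    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    row_ids = [str(r) for r in df.index]
    _check_unique(row_ids, row_what)

    def _parse(cell):  # exact (correctly rounded) float parsing
        try:
            return float(cell)
        except (TypeError, ValueError):
            return np.nan

    numeric = df.map(_parse)
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {row_ids[i]!r}, column {col_ids[j]!r}: "
            f"{df.iloc[i, j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing value at row {row_ids[i]!r}, column {col_ids[j]!r}")

    values = numeric.to_numpy(dtype=float)
    if orientation == "genes_by_samples":
        return ExpressionMatrix(values.T, tuple(row_ids), tuple(col_ids))
    return ExpressionMatrix(values, tuple(col_ids), tuple(row_ids))


def write_expression_table(
    matrix: ExpressionMatrix,
    path: str | Path,
    orientation: str = "samples_by_genes",
    delimiter: str | None = None,
) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = matrix.to_frame()
    if orientation == "genes_by_samples":
        df = df.T
    elif orientation != "samples_by_genes":
        raise ValueError(f"unknown orientation: {orientation!r}")
    # 17 significant digits: doubles survive the text round-trip bit-exactly
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_labels(path: str | Path, delimiter: str | None = None) -> dict[str, str]:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label table needs two columns: sample_id, class")
    sample_ids = [str(s) for s in df.iloc[:, 0]]
    _check_unique(sample_ids, "sample")
    return dict(zip(sample_ids, (str(c) for c in df.iloc[:, 1])))


def write_labels(dataset: LabeledDataset, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    pd.DataFrame(
        {"sample_id": list(dataset.matrix.sample_ids), "class": list(dataset.labels)}
    ).to_csv(path, sep=sep, index=False)


def labeled_dataset_from_files(
    expression_path: str | Path,
    labels_path: str | Path,
    orientation: str = "samples_by_genes",
    delimiter: str | None = None,
) -> LabeledDataset:
    matrix = read_expression_table(expression_path, orientation, delimiter)
    label_map = read_labels(labels_path, delimiter)
    missing = [s for s in matrix.sample_ids if s not in label_map]
    if missing:
        raise ValueError(f"samples without labels: {missing[:5]}")
    labels = tuple(label_map[s] for s in matrix.sample_ids)
    class_names = tuple(sorted(set(labels)))
    return LabeledDataset(matrix, labels, class_names)


def align_features(
    matrix: ExpressionMatrix,
    reference_genes: Sequence[str],
    missing_policy: str = "drop",
) -> AlignmentResult:
    """Reorder/subset columns to a reference gene list.

    Mirrors gene-list harmonization between cohorts quantified on different
    gene sets: with ``drop``, reference genes absent from the matrix are
    omitted and reported; with ``error``, any absence aborts.
    """
    reference = [str(g) for g in reference_genes]
    if not reference:
        raise ValueError("reference gene list is empty")
    if missing_policy not in ("drop", "error"):
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    have = set(matrix.gene_ids)
    missing = tuple(g for g in reference if g not in have)
    if missing and missing_policy == "error":
        raise ValueError(f"reference genes missing from matrix: {list(missing)}")
    kept = [g for g in reference if g in have]
    if not kept:
        raise ValueError("no overlap between matrix genes and reference list")
    return AlignmentResult(matrix.subset_genes(kept), missing)


def _per_class_indices(dataset: LabeledDataset) -> dict[str, np.ndarray]:
    labels = np.asarray(dataset.labels)
    return {
        c: np.flatnonzero(labels == c)
        for c in dataset.class_names
        if (labels == c).any()
    }


def stratified_split(
    dataset: LabeledDataset, train_fraction: float, seed: int
) -> SplitResult:
    """Deterministic stratified split with floor + largest-remainder rounding.

    Per-class proportions in train and test match the full data within one
    sample, so an 80:20 split of balanced classes is exact.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    by_class = _per_class_indices(dataset)
    for c, idx in by_class.items():
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has a single sample; cannot stratify")

    rng = np.random.default_rng(seed)
    classes = [c for c in dataset.class_names if c in by_class]
    quotas = {c: train_fraction * len(by_class[c]) for c in classes}
    take = {c: int(np.floor(quotas[c])) for c in classes}
    total_target = int(round(train_fraction * dataset.n_samples))
    leftover = total_target - sum(take.values())
    # largest fractional remainder first; ties broken by class order
    order = sorted(classes, key=lambda c: (-(quotas[c] - take[c]), classes.index(c)))
    for c in order[: max(leftover, 0)]:
        take[c] += 1

    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in classes:
        idx = by_class[c].copy()
        rng.shuffle(idx)
        n = min(max(take[c], 1), len(idx) - 1)  # keep both sides non-empty per class
        train_idx.extend(idx[:n].tolist())
        test_idx.extend(idx[n:].tolist())
    train_idx.sort()
    test_idx.sort()
    return SplitResult(
        train=dataset.subset(train_idx),
        test=dataset.subset(test_idx),
        seed=seed,
        train_fraction=train_fraction,
    )


def kfold_indices(dataset: LabeledDataset, k: int, seed: int) -> list[np.ndarray]:
    """Stratified k-fold partition of sample indices (the CV used throughout)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = {c: n for c, n in dataset.class_counts().items() if n > 0}
    small = sorted(c for c, n in counts.items() if n < k)
    if small:
        raise ValueError(f"classes with fewer than k={k} samples: {small}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    y = np.asarray(dataset.labels)
    return [test for _, test in splitter.split(np.zeros(len(y)), y)]
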