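"""Synthetic multi-class expression cohorts with a closed-form error oracle.

The generator emulates the statistical structure a pan-cancer expression
classifier sees: class-specific mean signatures on a minority of informative
genes in log2(x+1) space, shared baseline on the rest, isotropic Gaussian
within-class noise, optional class imbalance, and designated confusable
class pairs whose mean signatures overlap (the analogue of anatomically
adjacent tumour types that get mutually misclassified).

Because the noise is isotropic and shared, the two-class equal-prior Bayes
error has the closed form Phi(-d/2) with d the Mahalanobis distance between
class means; that is the oracle simulations are checked against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .data import ExpressionMatrix, LabeledDataset, write_expression_table, write_labels

__all__ = [
    "SyntheticSpec",
    "class_mean_matrix",
    "generate_cohort",
    "theoretical_pairwise_bayes_error",
    "nearest_centroid_predict",
    "nearest_centroid_error",
    "write_cohort",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic labeled expression cohort.

    mean_shift and noise_sd are in log2 units.  Informative genes occupy the
    first ``n_informative`` columns; each class's signature on them is a
    Rademacher sign pattern times ``mean_shift`` around ``baseline_mean``.
    A confusable pair (a, b, omega) blends class b's signature toward a's:
    omega = 1 makes the two classes identically distributed.
    """

    n_classes: int = 5
    samples_per_class: tuple[int, ...] = (200, 200, 200, 200, 200)
    n_genes: int = 100
    n_informative: int = 20
    mean_shift: float = 4.0
    noise_sd: float = 1.0
    confusable_pairs: tuple[tuple[int, int, float], ...] = ()
    baseline_mean: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples_per_class", tuple(int(n) for n in self.samples_per_class))
        object.__setattr__(
            self,
            "confusable_pairs",
            tuple((int(a), int(b), float(w)) for a, b, w in self.confusable_pairs),
        )
        if self.n_classes < 2:
            raise ValueError("need >= 2 classes")
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class length must equal n_classes")
        if any(n < 1 for n in self.samples_per_class):
            raise ValueError("every class needs >= 1 sample")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError("need 0 <= n_informative <= n_genes")
        if self.mean_shift < 0 or self.baseline_mean < 0:
            raise ValueError("mean_shift and baseline_mean must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for a, b, w in self.confusable_pairs:
            if not (0 <= a < self.n_classes and 0 <= b < self.n_classes) or a == b:
                raise ValueError(f"bad confusable pair ({a}, {b})")
            if not 0 <= w <= 1:
                raise ValueError("overlap factor must be in [0, 1]")

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(f"C{k + 1}" for k in range(self.n_classes))

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(f"G{j + 1:04d}" for j in range(self.n_genes))

    @property
    def informative_genes(self) -> tuple[str, ...]:
        return self.gene_ids[: self.n_informative]

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "samples_per_class": list(self.samples_per_class),
            "n_genes": self.n_genes,
            "n_informative": self.n_informative,
            "mean_shift": self.mean_shift,
            "noise_sd": self.noise_sd,
            "confusable_pairs": [list(p) for p in self.confusable_pairs],
            "baseline_mean": self.baseline_mean,
            "seed": self.seed,
        }


def class_mean_matrix(spec: SyntheticSpec) -> np.ndarray:
    """The (n_classes, n_genes) matrix of true class means, seed-determined."""
    rng = np.random.default_rng([spec.seed, 0])
    signs = rng.choice([-1.0, 1.0], size=(spec.n_classes, spec.n_informative))
    shifts = signs * spec.mean_shift
    for a, b, w in spec.confusable_pairs:
        shifts[b] = (1.0 - w) * shifts[b] + w * shifts[a]
    means = np.full((spec.n_classes, spec.n_genes), spec.baseline_mean, dtype=float)
    means[:, : spec.n_informative] += shifts
    return means


def generate_cohort(spec: SyntheticSpec) -> LabeledDataset:
    """Draw a labeled cohort: class mean + N(0, noise_sd^2), clipped at 0."""
    means = class_mean_matrix(spec)
    rng = np.random.default_rng([spec.seed, 1])
    blocks: list[np.ndarray] = []
    labels: list[str] = []
    for k, n_k in enumerate(spec.samples_per_class):
        noise = rng.normal(0.0, spec.noise_sd, size=(n_k, spec.n_genes))
        blocks.append(np.clip(means[k] + noise, 0.0, None))
        labels.extend([spec.class_names[k]] * n_k)
    values = np.vstack(blocks)
    sample_ids = tuple(f"S{i + 1:05d}" for i in range(values.shape[0]))
    matrix = ExpressionMatrix(values, spec.gene_ids, sample_ids)
    return LabeledDataset(matrix, tuple(labels), spec.class_names)


def _class_index(spec: SyntheticSpec, cls: int | str) -> int:
    if isinstance(cls, str):
        try:
            return spec.class_names.index(cls)
        except ValueError:
            raise ValueError(f"unknown class {cls!r}") from None
    if not 0 <= int(cls) < spec.n_classes:
        raise ValueError(f"class index {cls} out of range")
    return int(cls)


def theoretical_pairwise_bayes_error(
    spec: SyntheticSpec, class_a: int | str, class_b: int | str
) -> float:
    """Equal-prior two-class Gaussian Bayes error Phi(-d/2).

    d is the Euclidean distance between the two class mean vectors divided
    by noise_sd.  Truncation at zero is ignored; it is negligible whenever
    baseline_mean is several noise_sd above zero.
    """
    a = _class_index(spec, class_a)
    b = _class_index(spec, class_b)
    if a == b:
        raise ValueError("the two classes must be distinct")
    means = class_mean_matrix(spec)
    d = float(np.linalg.norm(means[a] - means[b])) / spec.noise_sd
    return float(norm.cdf(-d / 2.0))


def nearest_centroid_predict(values: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Class indices by nearest true class mean (the simulation oracle)."""
    d2 = ((values[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def nearest_centroid_error(dataset: LabeledDataset, spec: SyntheticSpec) -> float:
    """Empirical misclassification rate of the true-centroid classifier."""
    means = class_mean_matrix(spec)
    pred = nearest_centroid_predict(dataset.matrix.values, means)
    return float(np.mean(pred != dataset.label_indices()))


def write_cohort(dataset: LabeledDataset, spec: SyntheticSpec, outdir: str | Path) -> None:
    """Persist a cohort as TSV plus a JSON sidecar with the full spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_table(dataset.matrix, outdir / "expression.tsv")
    write_labels(dataset, outdir / "labels.tsv")
    with open(outdir / "cohort_spec.json", "w") as fh:
        json.dump(spec.to_dict(), fh, indent=2)
        fh.write("\n")
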