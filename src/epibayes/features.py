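"""Two-step PCA-loading + logistic-regression feature selection.

Step 1 screens the full matrix: PCA (gene-wise centering, no variance
scaling) on up to 10 components, genes ranked by absolute factor loading,
and an L2 logistic-regression classifier run under stratified k-fold CV at
a grid of gene counts; the smallest count whose CV accuracy is within a
plateau tolerance of the best is kept.  Step 2 repeats the whole procedure
on the matrix restricted to the step-1 genes, yielding the final compact
marker panel.  A single-gene screen evaluates every gene alone as a
classifier and flags (gene, class) pairs whose one-vs-rest precision and
recall both exceed a threshold (default 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .data import ExpressionMatrix, LabeledDataset, kfold_indices

__all__ = [
    "FeatureSelectionResult",
    "pca_top_loading_genes",
    "cv_accuracy_for_gene_counts",
    "choose_plateau_count",
    "two_step_select",
    "single_feature_screen",
]

DEFAULT_PER_COMPONENT_GRID = (1, 2, 5, 10, 20, 50)


@dataclass(frozen=True)
class FeatureSelectionResult:
    step1_genes: tuple[str, ...]
    selected_genes: tuple[str, ...]
    accuracy_trace: dict[str, dict[int, float]]  # {"step1": {...}, "step2": {...}}
    n_components: int
    plateau_tolerance: float

    def __post_init__(self) -> None:
        if not set(self.selected_genes) <= set(self.step1_genes):
            raise ValueError("selected_genes must be a subset of step1_genes")


def _component_loadings(matrix: ExpressionMatrix, n_components: int) -> np.ndarray:
    n_components = int(n_components)
    max_rank = min(matrix.n_samples, matrix.n_genes)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_genes)={max_rank}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(matrix.values)  # PCA centers gene-wise; no variance scaling
    return pca.components_  # (n_components, n_genes)


def pca_top_loading_genes(
    matrix: ExpressionMatrix, n_components: int, genes_per_component: int
) -> tuple[str, ...]:
    """Union of each component's top-|loading| genes.

    Ordered by (component index, |loading| descending); a gene retained by
    several components keeps its first (lowest-index) slot.
    """
    if genes_per_component < 1:
        raise ValueError("genes_per_component must be >= 1")
    loadings = _component_loadings(matrix, n_components)
    chosen: list[str] = []
    seen: set[str] = set()
    for comp in loadings:
        order = np.argsort(-np.abs(comp), kind="stable")[:genes_per_component]
        for j in order:
            g = matrix.gene_ids[j]
            if g not in seen:
                seen.add(g)
                chosen.append(g)
    return tuple(chosen)


def _interleaved_ranking(matrix: ExpressionMatrix, n_components: int) -> tuple[str, ...]:
    """Full gene ranking: round-robin over components, top-|loading| first.

    Prefixes of this ranking approximate 'g genes per component' for
    growing g, which is what the count grids below scan.
    """
    loadings = _component_loadings(matrix, n_components)
    per_comp = [np.argsort(-np.abs(comp), kind="stable") for comp in loadings]
    ranked: list[str] = []
    seen: set[int] = set()
    for depth in range(matrix.n_genes):
        for order in per_comp:
            j = int(order[depth])
            if j not in seen:
                seen.add(j)
                ranked.append(matrix.gene_ids[j])
    return tuple(ranked)


def _cv_classifier() -> LogisticRegression:
    # raw log2(x+1) values, unit L2 penalty (sklearn default); no feature
    # scaling — rescaling would equalize informative and noise genes
    return LogisticRegression(C=1.0, max_iter=2000)


def cv_accuracy_for_gene_counts(
    dataset: LabeledDataset,
    gene_ranking: Sequence[str],
    counts_grid: Sequence[int],
    k: int = 5,
    seed: int = 0,
) -> dict[int, float]:
    """Mean k-fold CV accuracy of L2 logistic regression on ranked-gene prefixes."""
    counts = [int(m) for m in counts_grid]
    if not counts:
        raise ValueError("counts_grid is empty")
    if max(counts) > len(gene_ranking):
        raise ValueError("counts_grid exceeds the length of gene_ranking")
    folds = kfold_indices(dataset, k, seed)
    all_idx = np.arange(dataset.n_samples)
    y = np.asarray(dataset.labels)
    gene_pos = {g: j for j, g in enumerate(dataset.matrix.gene_ids)}
    trace: dict[int, float] = {}
    for m in counts:
        cols = [gene_pos[g] for g in gene_ranking[:m]]
        X = dataset.matrix.values[:, cols]
        accs = []
        for test_idx in folds:
            train_idx = np.setdiff1d(all_idx, test_idx)
            clf = _cv_classifier()
            clf.fit(X[train_idx], y[train_idx])
            accs.append(float(np.mean(clf.predict(X[test_idx]) == y[test_idx])))
        trace[m] = float(np.mean(accs))
    return trace


def choose_plateau_count(trace: dict[int, float], tolerance: float) -> int:
    """Smallest gene count whose accuracy is within ``tolerance`` of the best."""
    if not trace:
        raise ValueError("accuracy trace is empty")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    best = max(trace.values())
    for m in sorted(trace):
        if trace[m] >= best - tolerance:
            return m
    raise AssertionError("unreachable: the maximum itself always qualifies")


def _default_grid(n_components: int, pool_size: int) -> list[int]:
    counts = sorted({min(g * n_components, pool_size) for g in DEFAULT_PER_COMPONENT_GRID})
    return [c for c in counts if c >= 1]


def two_step_select(
    dataset: LabeledDataset,
    n_components: int = 10,
    step1_grid: Sequence[int] | None = None,
    step2_grid: Sequence[int] | None = None,
    k: int = 5,
    tolerance: float = 0.01,
    seed: int = 0,
) -> FeatureSelectionResult:
    """Two-stage selection; step 2 refits PCA on the step-1 gene subset."""
    n_comp1 = min(n_components, dataset.n_samples, dataset.matrix.n_genes)
    ranking1 = _interleaved_ranking(dataset.matrix, n_comp1)
    grid1 = list(step1_grid) if step1_grid is not None else _default_grid(
        n_comp1, dataset.matrix.n_genes
    )
    trace1 = cv_accuracy_for_gene_counts(dataset, ranking1, grid1, k, seed)
    c1 = choose_plateau_count(trace1, tolerance)
    step1_genes = ranking1[:c1]

    reduced = dataset.restrict_genes(step1_genes)
    n_comp2 = min(n_components, reduced.n_samples, len(step1_genes))
    ranking2 = _interleaved_ranking(reduced.matrix, n_comp2)
    grid2 = list(step2_grid) if step2_grid is not None else _default_grid(
        n_comp2, len(step1_genes)
    )
    grid2 = sorted({min(m, len(step1_genes)) for m in grid2})
    trace2 = cv_accuracy_for_gene_counts(reduced, ranking2, grid2, k, seed)
    c2 = choose_plateau_count(trace2, tolerance)
    selected = ranking2[:c2]

    return FeatureSelectionResult(
        step1_genes=step1_genes,
        selected_genes=selected,
        accuracy_trace={"step1": trace1, "step2": trace2},
        n_components=n_components,
        plateau_tolerance=tolerance,
    )


def single_feature_screen(
    dataset: LabeledDataset,
    pr_threshold: float = 0.75,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """One-gene classifiers under k-fold CV, scored per (gene, class).

    Pooled held-out predictions give one-vs-rest precision/recall/F1 per
    (gene, class); pairs with both precision and recall above the
    threshold are flagged as qualifying.
    """
    folds = kfold_indices(dataset, k, seed)
    all_idx = np.arange(dataset.n_samples)
    y = np.asarray(dataset.labels)
    rows = []
    for j, gene in enumerate(dataset.matrix.gene_ids):
        X = dataset.matrix.values[:, [j]]
        pooled = np.empty(dataset.n_samples, dtype=object)
        for test_idx in folds:
            train_idx = np.setdiff1d(all_idx, test_idx)
            clf = _cv_classifier()
            clf.fit(X[train_idx], y[train_idx])
            pooled[test_idx] = clf.predict(X[test_idx])
        for c in dataset.class_names:
            tp = int(np.sum((pooled == c) & (y == c)))
            fp = int(np.sum((pooled == c) & (y != c)))
            fn = int(np.sum((pooled != c) & (y == c)))
            precision = tp / (tp + fp) if tp + fp else 0.0
            recall = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
            rows.append(
                {
                    "gene": gene,
                    "class": c,
                    "precision": precision,
                    "recall": recall,
                    "f1": f1,
                    "qualifies": precision > pr_threshold and recall > pr_threshold,
                }
            )
    return pd.DataFrame(rows)
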