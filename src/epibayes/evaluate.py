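"""Confusion-matrix metrics and classification reports.

Convention: confusion rows are actual classes, columns predicted classes.
Overall accuracy is the fraction of correct predictions, i.e. the trace of
the confusion matrix over its total.  Per-class precision/recall/F1 are
one-vs-rest; zero-denominator cases are reported as 0 with a flag instead
of NaN so per-class tables stay total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClassificationReport",
    "confusion",
    "precision_recall_f1",
    "overall_accuracy",
    "build_report",
]


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str], class_names: Sequence[str]
) -> np.ndarray:
    """Count matrix: entry (a, p) counts samples with actual a, predicted p."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    pos = {c: i for i, c in enumerate(class_names)}
    unknown = sorted({y for y in (*y_true, *y_pred) if y not in pos})
    if unknown:
        raise ValueError(f"labels outside the class alphabet: {unknown}")
    mat = np.zeros((len(pos), len(pos)), dtype=int)
    for a, p in zip(y_true, y_pred):
        mat[pos[a], pos[p]] += 1
    return mat


def precision_recall_f1(conf: np.ndarray) -> pd.DataFrame:
    """One-vs-rest P, R, F1 per class from a confusion matrix."""
    conf = np.asarray(conf)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1] or (conf < 0).any():
        raise ValueError("confusion must be a square non-negative count matrix")
    tp = np.diag(conf).astype(float)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.maximum(pr, 1e-300), 0.0)
    return pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "zero_denominator": (tp + fp == 0) | (tp + fn == 0),
        }
    )


def overall_accuracy(y_true: Sequence[str], y_pred: Sequence[str]) -> float:
    y_true = list(y_true)
    y_pred = list(y_pred)
    if not y_true or len(y_true) != len(y_pred):
        raise ValueError("need equal, non-zero numbers of true and predicted labels")
    return float(np.mean([a == b for a, b in zip(y_true, y_pred)]))


@dataclass(frozen=True)
class ClassificationReport:
    class_names: tuple[str, ...]
    confusion: np.ndarray
    per_class: pd.DataFrame
    overall_accuracy: float
    retained_fraction: float = 1.0
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "confusion": self.confusion.tolist(),
            "per_class": {
                c: {
                    "precision": float(self.per_class.loc[i, "precision"]),
                    "recall": float(self.per_class.loc[i, "recall"]),
                    "f1": float(self.per_class.loc[i, "f1"]),
                }
                for i, c in enumerate(self.class_names)
            },
            "overall_accuracy": self.overall_accuracy,
            "retained_fraction": self.retained_fraction,
            "provenance": self.provenance,
        }

    def write(self, outdir: str | Path, stem: str) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        conf = pd.DataFrame(
            self.confusion, index=list(self.class_names), columns=list(self.class_names)
        )
        conf.to_csv(outdir / f"{stem}_confusion.tsv", sep="\t")
        per_class = self.per_class.copy()
        per_class.insert(0, "class", list(self.class_names))
        per_class.to_csv(outdir / f"{stem}_per_class.tsv", sep="\t", index=False)
        with open(outdir / f"{stem}_summary.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def build_report(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    class_names: Sequence[str],
    retained_fraction: float = 1.0,
    provenance: dict | None = None,
) -> ClassificationReport:
    conf = confusion(y_true, y_pred, class_names)
    return ClassificationReport(
        class_names=tuple(class_names),
        confusion=conf,
        per_class=precision_recall_f1(conf),
        overall_accuracy=overall_accuracy(y_true, y_pred),
        retained_fraction=float(retained_fraction),
        provenance=provenance or {},
    )
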