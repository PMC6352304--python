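"""Validation of delineation against known species labels.

Every unordered genome pair is classified at a similarity threshold:

* TP — similarity above the threshold, same species;
* TN — similarity below (or at) the threshold, different species;
* FP — similarity above the threshold, different species;
* FN — similarity below (or at) the threshold, same species.

Sensitivity is ``100 * TP / (TP + FN)`` and specificity ``100 * TN /
(TN + FP)``; both are ``None`` (flagged, not silently 0 or 100) when their
denominator is empty.  Sweeping the threshold over a grid (default 90-98% in
0.5% steps, 17 points) yields an ROC curve, conventionally plotted as
sensitivity against 100 - specificity.  Along an increasing threshold the
sensitivity is non-increasing and the specificity non-decreasing, directly
from the definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .delineation import ParameterSubset, SimilarityMatrix, similarity_matrix
from .parameters import PARAMETER_NAMES, GenomeParameters

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "confusion",
    "threshold_grid",
    "roc_sweep",
    "subset_comparison_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pair-level confusion counts at one similarity threshold."""

    tp: int
    tn: int
    fp: int
    fn: int
    threshold: float

    @property
    def sensitivity(self) -> float | None:
        """Percent of same-species pairs called same; None if no such pairs."""
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        """Percent of different-species pairs called different; None if none."""
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else None

    @property
    def n_pairs(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ROCCurve:
    """Sensitivity/specificity across a threshold sweep."""

    points: tuple[ConfusionCounts, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": [p.threshold for p in self.points],
                "sensitivity": [p.sensitivity for p in self.points],
                "specificity": [p.specificity for p in self.points],
                "tp": [p.tp for p in self.points],
                "tn": [p.tn for p in self.points],
                "fp": [p.fp for p in self.points],
                "fn": [p.fn for p in self.points],
            }
        )


def _pair_data(
    matrix: SimilarityMatrix, labels: dict[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    missing = [g for g in matrix.genome_ids if g not in labels]
    if missing:
        raise ValueError(f"missing species label for genome(s): {missing}")
    n = len(matrix.genome_ids)
    if n < 2:
        raise ValueError("need at least one genome pair")
    iu, ju = np.triu_indices(n, k=1)
    sims = matrix.values[iu, ju]
    lab = np.array([labels[g] for g in matrix.genome_ids])
    same = lab[iu] == lab[ju]
    return sims, same


def confusion(
    matrix: SimilarityMatrix, labels: dict[str, str], threshold: float
) -> ConfusionCounts:
    """Classify every unordered pair of the matrix at one threshold."""
    sims, same = _pair_data(matrix, labels)
    above = sims > threshold
    return ConfusionCounts(
        tp=int(np.count_nonzero(above & same)),
        tn=int(np.count_nonzero(~above & ~same)),
        fp=int(np.count_nonzero(above & ~same)),
        fn=int(np.count_nonzero(~above & same)),
        threshold=float(threshold),
    )


def threshold_grid(t_min: float = 90.0, t_max: float = 98.0, step: float = 0.5) -> np.ndarray:
    """Inclusive threshold grid built by integer stepping (no float drift)."""
    if not (t_min < t_max and step > 0):
        raise ValueError("require t_min < t_max and step > 0")
    n = int(round((t_max - t_min) / step))
    if abs(t_min + n * step - t_max) > 1e-9:
        n = int(np.floor((t_max - t_min) / step + 1e-9))
    return t_min + step * np.arange(n + 1)


def roc_sweep(
    matrix: SimilarityMatrix,
    labels: dict[str, str],
    t_min: float = 90.0,
    t_max: float = 98.0,
    step: float = 0.5,
) -> ROCCurve:
    """Confusion counts over the threshold grid (defaults: 17 points)."""
    return ROCCurve(
        points=tuple(confusion(matrix, labels, t) for t in threshold_grid(t_min, t_max, step))
    )


def subset_comparison_report(
    params: list[GenomeParameters],
    labels: dict[str, str],
    subsets: list[ParameterSubset | str] | None = None,
    t_min: float = 90.0,
    t_max: float = 98.0,
    step: float = 0.5,
) -> pd.DataFrame:
    """Sensitivity/specificity per threshold for several parameter subsets.

    By default covers each single parameter plus the s2/s3/s4 combinations,
    one row per (subset, threshold) — the tabular companion of the ROC plot.
    """
    if subsets is None:
        subsets = [*PARAMETER_NAMES, "s2", "s3", "s4"]
    frames = []
    for sub in subsets:
        name = sub if isinstance(sub, str) else ",".join(sub.members)
        mat = similarity_matrix(params, sub)
        frame = roc_sweep(mat, labels, t_min, t_max, step).to_frame()
        frame.insert(0, "subset", name)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
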