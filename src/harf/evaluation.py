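"""Confusion matrices and accuracy aggregation.

The headline number for this kind of recognizer is the *macro* (unweighted
per-class) accuracy: the mean of the row-normalized confusion-matrix
diagonal, optionally extended with extra per-class accuracies that were
tabulated separately (here: the four location-based activities, which are
evaluated by geometry rather than by the statistical classifier).  A
micro-averaged accuracy (pooled window counts) is provided as a secondary
view.

The module also ships, as a verbatim fixture, the published row-normalized
validation matrix for the 11 location-qualified physical activities; its
diagonal mean is 90.40% and appending 100% for each of the four venue
activities gives 92.96%.  One printed row (Home/Sitting) sums to 101.00 —
the values are preserved exactly as printed rather than repaired, and the
diagonal (hence both aggregates) is unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


def normalize_rows(matrix: np.ndarray) -> np.ndarray:
    """Scale each row to sum to 100; all-zero rows are left at zero."""
    matrix = np.asarray(matrix, dtype=float)
    sums = matrix.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, matrix / sums * 100.0, 0.0)
    return out


@dataclass
class ConfusionMatrix:
    """Counts[i][j] = windows of true label i predicted as label j.

    Either count-backed (built from aligned label sequences) or
    percentage-backed (loaded from a report or fixture, counts unknown).
    """

    labels: tuple
    counts: Optional[np.ndarray] = None
    _percentages: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        n = len(self.labels)
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if self.counts.shape != (n, n):
                raise ValueError("counts shape must match label count")
            if np.any(self.counts < 0):
                raise ValueError("counts must be >= 0")
        if self._percentages is not None:
            self._percentages = np.asarray(self._percentages, dtype=float)
            if self._percentages.shape != (n, n):
                raise ValueError("percentage shape must match label count")
        if self.counts is None and self._percentages is None:
            raise ValueError("need counts or percentages")

    @classmethod
    def from_percentages(cls, labels, percentages) -> "ConfusionMatrix":
        """Wrap an already row-normalized percentage matrix (verbatim)."""
        return cls(labels=tuple(labels), counts=None, _percentages=percentages)

    def percentages(self) -> np.ndarray:
        """Row-normalized percentage view."""
        if self.counts is not None:
            return normalize_rows(self.counts)
        return self._percentages.copy()

    def diagonal_percent(self) -> np.ndarray:
        return np.diag(self.percentages())

    def per_class_accuracy(self) -> dict:
        return {lab: float(v) for lab, v in zip(self.labels, self.diagonal_percent())}


def build_confusion(
    truth: Sequence[str], pred: Sequence[str], labels: Sequence[str] | None = None
) -> ConfusionMatrix:
    """Count-backed confusion matrix from aligned label sequences.

    ``labels`` fixes the row/column order; labels observed in the data but
    not declared are appended in sorted order.
    """
    truth = list(truth)
    pred = list(pred)
    if len(truth) != len(pred):
        raise ValueError(
            f"truth and prediction lengths differ ({len(truth)} vs {len(pred)})"
        )
    declared = list(labels) if labels is not None else []
    observed = sorted((set(truth) | set(pred)) - set(declared))
    order = declared + [l for l in observed if l not in declared]
    index = {l: i for i, l in enumerate(order)}
    counts = np.zeros((len(order), len(order)), dtype=np.int64)
    for t, p in zip(truth, pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(labels=tuple(order), counts=counts)


def macro_accuracy(cm, extra_diagonals: Sequence[float] | None = None) -> float:
    """Unweighted mean of per-class accuracies, in percent.

    ``cm`` is a :class:`ConfusionMatrix` or a row-normalized percentage
    matrix.  ``extra_diagonals`` appends per-class accuracies evaluated
    outside the matrix (each in [0, 100]).  For a count-backed matrix,
    classes with no true windows are excluded from the mean.
    """
    if isinstance(cm, ConfusionMatrix):
        diag = cm.diagonal_percent()
        if cm.counts is not None:
            present = cm.counts.sum(axis=1) > 0
            diag = diag[present]
    else:
        diag = np.diag(np.asarray(cm, dtype=float))
    diag = list(diag)
    if extra_diagonals is not None:
        for v in extra_diagonals:
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"extra diagonal entry {v} outside [0, 100]")
            diag.append(float(v))
    if len(diag) == 0:
        raise ValueError("macro accuracy of an empty diagonal")
    return float(np.mean(diag))


def micro_accuracy(cm: ConfusionMatrix) -> float:
    """Pooled window accuracy in percent (requires a count-backed matrix)."""
    if cm.counts is None:
        raise ValueError("micro accuracy requires counts")
    total = cm.counts.sum()
    if total == 0:
        raise ValueError("micro accuracy of an empty matrix")
    return float(np.trace(cm.counts) / total * 100.0)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def write_confusion(cm: ConfusionMatrix, path) -> None:
    """Row/column-labeled CSV of row-normalized percentages (2 decimals)."""
    df = pd.DataFrame(
        np.round(cm.percentages(), 2), index=cm.labels, columns=cm.labels
    )
    df.to_csv(path, index_label="label", float_format="%.2f")


def read_confusion(path) -> ConfusionMatrix:
    df = pd.read_csv(path, index_col="label")
    return ConfusionMatrix.from_percentages(tuple(df.index), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# published 11-activity validation fixture
# ---------------------------------------------------------------------------

PUBLISHED_LABELS_11 = (
    "Home/Standing", "Home/Walking", "Home/Sitting",
    "Office/Standing", "Office/Walking", "Office/Sitting",
    "Outdoor/Standing", "Outdoor/Walking", "Outdoor/Sitting",
    "Outdoor/Jogging", "Riding a car",
)

# Verbatim transcription ('-' entries are 0).  Note: the Home/Sitting row
# sums to 101.00 as printed; it is deliberately not repaired.
PUBLISHED_CONFUSION_11 = np.array([
    [90.32, 0.00, 9.68, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00],
    [10.43, 83.47, 6.10, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00],
    [2.56, 0.00, 98.44, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00],
    [0.00, 0.00, 0.00, 95.20, 0.00, 4.80, 0.00, 0.00, 0.00, 0.00, 0.00],
    [0.00, 0.00, 0.00, 4.84, 94.35, 0.81, 0.00, 0.00, 0.00, 0.00, 0.00],
    [0.00, 0.00, 0.00, 1.20, 0.61, 98.19, 0.00, 0.00, 0.00, 0.00, 0.00],
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 94.34, 0.00, 5.66, 0.00, 0.00],
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 12.77, 80.85, 6.38, 0.00, 0.00],
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 2.50, 0.00, 97.50, 0.00, 0.00],
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 2.17, 10.86, 1.47, 85.50, 0.00],
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 16.25, 6.25, 1.25, 0.00, 76.25],
])


def published_confusion_11() -> ConfusionMatrix:
    """The published 11-activity validation matrix as a ConfusionMatrix."""
    return ConfusionMatrix.from_percentages(PUBLISHED_LABELS_11, PUBLISHED_CONFUSION_11)
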