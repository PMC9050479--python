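"""Image-wise cancer-region identification and evaluation metrics.

A field of view is called cancerous when the fraction of its nuclei
classified cancerous, N_C / N_Total, reaches a threshold.  The threshold
is chosen on validation images from a small candidate set (1%, 5%, 10%,
20%, 30%) by maximizing the number of correctly classified images, with
ties broken toward the smaller candidate — a larger threshold trades
false positives for false negatives, and missing cancer is the costlier
error.  Images with no detected nuclei are 'indeterminate' rather than
normal: absence of nuclei is absence of evidence.

Positive = cancerous, negative = normal throughout:

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ImagewiseResult",
    "ConfusionCounts",
    "Metrics",
    "DEFAULT_THRESHOLD_CANDIDATES",
    "classify_image",
    "select_image_threshold",
    "compute_metrics",
    "roc_auc",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_CANDIDATES = (0.01, 0.05, 0.10, 0.20, 0.30)


@dataclass
class ImagewiseResult:
    image_id: str
    n_cancer: int
    n_total: int
    fraction: float | None
    decision: str  # cancerous / normal / indeterminate
    threshold: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_cancer <= self.n_total:
            raise ValueError(
                f"n_cancer={self.n_cancer} outside [0, n_total={self.n_total}]"
            )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float  # NaN when undefined
    specificity: float  # NaN when undefined

    @property
    def sensitivity_defined(self) -> bool:
        return not np.isnan(self.sensitivity)

    @property
    def specificity_defined(self) -> bool:
        return not np.isnan(self.specificity)


def classify_image(
    decisions: np.ndarray | list,
    threshold: float,
    image_id: str = "",
) -> ImagewiseResult:
    """Decide cancerous/normal for one image from per-nucleus calls.

    ``decisions`` holds one boolean (or 0/1) per detected nucleus, True
    meaning classified cancerous.  The image is cancerous iff
    ``N_C / N_Total >= threshold`` (inclusive); with zero nuclei the
    decision is 'indeterminate'.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    calls = np.asarray(decisions, dtype=bool).ravel()
    n_total = int(calls.size)
    n_cancer = int(calls.sum())
    if n_total == 0:
        return ImagewiseResult(image_id, 0, 0, None, "indeterminate", threshold)
    fraction = n_cancer / n_total
    decision = "cancerous" if fraction >= threshold else "normal"
    return ImagewiseResult(image_id, n_cancer, n_total, fraction, decision, threshold)


def select_image_threshold(
    fractions: np.ndarray | list,
    truths: np.ndarray | list,
    candidates: tuple[float, ...] = DEFAULT_THRESHOLD_CANDIDATES,
) -> float:
    """Pick the candidate maximizing correctly classified validation images.

    ``fractions`` are per-image cancerous-nucleus fractions; ``truths`` are
    booleans (True = cancerous image).  Ties go to the smaller threshold.
    """
    if len(candidates) == 0:
        raise ValueError("no threshold candidates")
    fractions = np.asarray(fractions, dtype=float)
    truths = np.asarray(truths, dtype=bool)
    if fractions.shape != truths.shape:
        raise ValueError("fractions and truths differ in length")
    best_thr = None
    best_correct = -1
    for thr in sorted(candidates):
        called = fractions >= thr
        correct = int((called == truths).sum())
        if correct > best_correct:  # strict: ties keep the smaller threshold
            best_correct = correct
            best_thr = thr
    return float(best_thr)


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity, specificity; undefined ratios come back NaN."""
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (counts.tp + counts.tn) / counts.total
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    sensitivity = counts.tp / pos if pos else float("nan")
    specificity = counts.tn / neg if neg else float("nan")
    if not pos:
        logger.warning("no positive records; sensitivity undefined")
    if not neg:
        logger.warning("no negative records; specificity undefined")
    return Metrics(accuracy, sensitivity, specificity)


def roc_auc(scores: np.ndarray | list, truths: np.ndarray | list) -> float:
    """Area under the ROC curve (rank-statistic / trapezoidal definition).

    Ties in score follow the rank-midpoint convention, i.e. the value
    equals U / (n_pos * n_neg) for the Mann-Whitney U of the positive
    scores.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truths = np.asarray(truths, dtype=bool).ravel()
    if scores.shape != truths.shape:
        raise ValueError("scores and truths differ in length")
    if truths.all() or not truths.any():
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(truths.astype(int), scores))
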