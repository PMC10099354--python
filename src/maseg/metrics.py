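"""Pixel-set segmentation metrics: TP/FP/FN by logical set operations,
intersection-over-union (Jaccard) and the Dice coefficient (F1).

The comparison is purely pixelwise over the whole image — no per-lesion
matching.  With ground truth GT and predicted mask S as pixel sets:

    TP = GT AND S
    FP = (GT OR S) - GT        (predicted outside the ground truth)
    FN = (GT OR S) - S         (ground truth the model missed)

    IoU  = TP / (TP + FP + FN)
    Dice = 2*TP / (2*TP + FP + FN) = 2*IoU / (1 + IoU)

Both scores live in [0, 1]; 0 means no overlap, 1 perfect overlap.  When
both masks are empty the ratios are 0/0; they are defined here as 1.0
(perfect agreement on absence) and flagged as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MetricCounts:
    """Pixel counts of the confusion sets."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_gt(self) -> int:
        """|GT| = TP + FN."""
        return self.tp + self.fn

    @property
    def n_pred(self) -> int:
        """|S| = TP + FP."""
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricReport:
    counts: MetricCounts
    iou: float
    dice: float
    degenerate: bool = False


def confusion_counts(gt: np.ndarray, s: np.ndarray) -> MetricCounts:
    """Count TP/FP/FN pixels between a ground-truth and a predicted mask."""
    gt = np.asarray(gt, dtype=bool)
    s = np.asarray(s, dtype=bool)
    if gt.shape != s.shape:
        raise ValueError(f"mask shape mismatch: {gt.shape} vs {s.shape}")
    tp = int(np.count_nonzero(gt & s))
    fp = int(np.count_nonzero(s & ~gt))
    fn = int(np.count_nonzero(gt & ~s))
    return MetricCounts(tp=tp, fp=fp, fn=fn)


def iou(counts: MetricCounts) -> float:
    """Jaccard index TP / (TP + FP + FN); 1.0 when both masks are empty."""
    denom = counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return counts.tp / denom


def dice(counts: MetricCounts) -> float:
    """Dice coefficient 2*TP / (2*TP + FP + FN); 1.0 when both masks are empty."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return 2 * counts.tp / denom


def report(gt: np.ndarray, s: np.ndarray) -> MetricReport:
    """Full metric report for one ground-truth / prediction pair."""
    counts = confusion_counts(gt, s)
    degenerate = (counts.tp + counts.fp + counts.fn) == 0
    return MetricReport(counts=counts, iou=iou(counts), dice=dice(counts),
                        degenerate=degenerate)
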