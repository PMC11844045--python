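"""Segmentation evaluation: confusion counts and the Acc/SP/SE/F1/MIoU set.

Counts are exact integer tallies over pixels (optionally restricted to
a field-of-view mask); metrics are computed once from pooled counts.
A zero denominator yields 0 with a warning rather than NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "confusion_counts", "compute_metrics"]

METRIC_NAMES = ("Acc", "SP", "SE", "F1", "MIoU")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def confusion_counts(pred_binary, y, fov_mask=None) -> ConfusionCounts:
    """Pixelwise TP/FP/TN/FN between a binary prediction and binary truth.

    If ``fov_mask`` is given only pixels inside it are counted.
    """
    pred = np.asarray(pred_binary).astype(bool)
    truth = np.asarray(y).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if fov_mask is not None:
        fov = np.asarray(fov_mask).astype(bool)
        if fov.shape != truth.shape:
            raise ValueError("fov mask shape mismatch")
        pred, truth = pred[fov], truth[fov]
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & truth)),
        fp=int(np.count_nonzero(pred & ~truth)),
        tn=int(np.count_nonzero(~pred & ~truth)),
        fn=int(np.count_nonzero(~pred & truth)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {name}; returning 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, specificity, sensitivity, F1 and mean IoU from counts.

    MIoU averages the vessel-class IoU TP/(TP+FP+FN) and the
    background-class IoU TN/(TN+FN+FP).
    """
    if min(c.tp, c.fp, c.tn, c.fn) < 0:
        raise ValueError("negative counts")
    if c.total == 0:
        raise ValueError("no pixels evaluated")
    return {
        "Acc": _ratio(c.tp + c.tn, c.total, "Acc"),
        "SP": _ratio(c.tn, c.tn + c.fp, "SP"),
        "SE": _ratio(c.tp, c.tp + c.fn, "SE"),
        "F1": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "F1"),
        "MIoU": 0.5 * (_ratio(c.tp, c.tp + c.fp + c.fn, "MIoU")
                       + _ratio(c.tn, c.tn + c.fn + c.fp, "MIoU")),
    }
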