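"""Fusion-quality statistics (spatial frequency, average gradient) and
classification reporting.

SF and AG both quantify the textural information of an image through its
first differences; a fused importance map that preserves detail from all
views scores higher than one that averages it away.  Definitional variants
abound in the fusion literature, so the exact conventions used here are
fixed:

* ``spatial_frequency``: RF = sqrt(Σ (horizontal differences)² / (M·N)),
  CF likewise vertically, SF = sqrt(RF² + CF²).
* ``average_gradient``: mean over the (M−1)(N−1) interior grid of
  sqrt((Δx² + Δy²)/2) with forward differences.

Both operate on intensities rescaled to [0, ``scale``]; the default scale
of 255 matches the 8-bit convention common in fusion benchmarks.  Both are
zero iff the image is constant, shift-invariant in intensity, and
homogeneous of degree 1 in ``scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

__all__ = [
    "FusionMetrics",
    "spatial_frequency",
    "average_gradient",
    "fusion_metrics",
    "ClassificationReport",
    "classification_report",
]

DEFAULT_SCALE = 255.0


def _check_image(image: np.ndarray) -> np.ndarray:
    x = np.asarray(image, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("metrics require a 2-D image with both sides >= 2")
    return x


def spatial_frequency(image: np.ndarray, scale: float = DEFAULT_SCALE) -> float:
    x = _check_image(image) * scale
    m, n = x.shape
    rf2 = np.sum(np.diff(x, axis=1) ** 2) / (m * n)
    cf2 = np.sum(np.diff(x, axis=0) ** 2) / (m * n)
    return float(np.sqrt(rf2 + cf2))


def average_gradient(image: np.ndarray, scale: float = DEFAULT_SCALE) -> float:
    x = _check_image(image) * scale
    dx = x[:-1, 1:] - x[:-1, :-1]
    dy = x[1:, :-1] - x[:-1, :-1]
    return float(np.mean(np.sqrt((dx**2 + dy**2) / 2.0)))


@dataclass(frozen=True)
class FusionMetrics:
    sf: float
    ag: float
    scale: float = DEFAULT_SCALE


def fusion_metrics(image: np.ndarray, scale: float = DEFAULT_SCALE) -> FusionMetrics:
    return FusionMetrics(
        sf=spatial_frequency(image, scale),
        ag=average_gradient(image, scale),
        scale=scale,
    )


# ---------------------------------------------------------------------------
# classification reporting
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Macro-averaged scores as percentages (one decimal), plus per-class
    detail and the confusion matrix."""

    f1: float
    recall: float
    precision: float
    accuracy: float
    per_class: dict = field(default_factory=dict)
    confusion: np.ndarray | None = None
    labels: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "f1": self.f1,
            "recall": self.recall,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "labels": [str(c) for c in self.labels],
            "confusion": None if self.confusion is None else self.confusion.tolist(),
        }


def classification_report(y_true, y_pred, class_names=None) -> ClassificationReport:
    """Macro precision/recall/F1 and accuracy, as percentages.

    A class with no predicted samples contributes zero precision (and hence
    zero F1) rather than NaN.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("cannot score an empty label set")
    labels = sorted(set(np.unique(y_true)) | set(np.unique(y_pred)))
    if len(np.unique(y_true)) < 2:
        raise ValueError("need at least two classes present in y_true")
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    p_c, r_c, f_c, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average=None, zero_division=0
    )
    conf = confusion_matrix(y_true, y_pred, labels=labels)
    acc = np.trace(conf) / conf.sum()
    names = (
        [str(c) for c in labels]
        if class_names is None
        else [str(class_names[c]) for c in labels]
    )
    per_class = {
        name: {
            "precision": round(100 * p, 1),
            "recall": round(100 * r, 1),
            "f1": round(100 * f, 1),
            "support": int(s),
        }
        for name, p, r, f, s in zip(names, p_c, r_c, f_c, support)
    }
    return ClassificationReport(
        f1=round(100 * f1, 1),
        recall=round(100 * rec, 1),
        precision=round(100 * prec, 1),
        accuracy=round(100 * acc, 1),
        per_class=per_class,
        confusion=conf,
        labels=list(labels),
    )
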