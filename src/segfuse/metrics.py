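"""Per-class segmentation metrics from pooled pixel confusion counts.

All metrics derive from a K×K :class:`ConfusionMatrix` accumulated over an
entire mask set (dataset-wide pooling, one number per predictor per class —
not per-image averages). For class c with TP = counts[c, c],
FP = column-sum − TP and FN = row-sum − TP:

* ``IoU(c)    = TP / (TP + FP + FN)``       (Jaccard index)
* ``F1(c)     = 2·TP / (2·TP + FP + FN)``   (Dice / harmonic mean of P and R)
* ``PREC(c)   = TP / (TP + FP)``
* ``RECALL(c) = TP / (TP + FN)``

A metric whose denominator is zero (class absent from both ground truth and
prediction) is *undefined* and represented as NaN — never coerced to 0 or 1,
and excluded from aggregates, since coercion silently biases weighted means.

The ranking aggregate is the **weighted IoU**: per-class IoU averaged with
ground-truth pixel-frequency weights, compensating for the severe pixel-count
imbalance between lesion classes and background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import ClassCatalog
from .masks import LabelMask

METRIC_NAMES = ("IoU", "F1", "PREC", "RECALL", "CORRECT_PCT")


@dataclass(frozen=True)
class ConfusionMatrix:
    """K×K pixel counts; rows = ground-truth class, cols = predicted class."""

    counts: np.ndarray
    catalog: ClassCatalog

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.catalog)
        if counts.shape != (k, k):
            raise ValueError(f"confusion counts must be {k}x{k}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total_pixels(self) -> int:
        return int(self.counts.sum())

    def tp(self) -> np.ndarray:
        return np.diag(self.counts).astype(np.int64)

    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp()

    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp()

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if other.catalog != self.catalog:
            raise ValueError("cannot add confusion matrices over different catalogs")
        return ConfusionMatrix(self.counts + other.counts, self.catalog)


@dataclass(frozen=True)
class MetricsTable:
    """N predictors × K classes of one metric; NaN marks undefined cells."""

    values: np.ndarray
    predictor_names: tuple[str, ...]
    catalog: ClassCatalog
    metric_name: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.predictor_names), len(self.catalog)):
            raise ValueError(
                f"values shape {values.shape} != "
                f"({len(self.predictor_names)}, {len(self.catalog)})"
            )
        defined = values[~np.isnan(values)]
        if ((defined < 0) | (defined > 1)).any():
            raise ValueError("metric values must lie in [0, 1]")
        if self.metric_name not in METRIC_NAMES:
            raise ValueError(f"unknown metric name {self.metric_name!r}")
        object.__setattr__(self, "values", values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.predictor_names), columns=list(self.catalog.names)
        )

    def row(self, predictor: str) -> np.ndarray:
        return self.values[self.predictor_names.index(predictor)]


@dataclass(frozen=True)
class ClassPixelWeights:
    """Per-class fraction of ground-truth pixels; defined entries sum to 1."""

    weights: np.ndarray
    catalog: ClassCatalog

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        if weights.shape != (len(self.catalog),):
            raise ValueError(f"need {len(self.catalog)} weights, got {weights.shape}")
        if (weights < 0).any():
            raise ValueError("weights must be non-negative")
        if not np.isclose(weights.sum(), 1.0, atol=1e-9):
            raise ValueError(f"weights must sum to 1, got {weights.sum()}")
        object.__setattr__(self, "weights", weights)


def accumulate_confusion(
    gt: Sequence[LabelMask], pred: Sequence[LabelMask], catalog: ClassCatalog
) -> ConfusionMatrix:
    """Pool pixel confusion counts over aligned (ground truth, prediction) pairs."""
    if len(gt) != len(pred):
        raise ValueError(f"mask list lengths differ: {len(gt)} vs {len(pred)}")
    if not gt:
        raise ValueError("empty mask lists")
    k = len(catalog)
    counts = np.zeros((k, k), dtype=np.int64)
    for i, (g, p) in enumerate(zip(gt, pred)):
        if g.shape != p.shape:
            raise ValueError(f"pair {i}: shape mismatch {g.shape} vs {p.shape}")
        joint = g.grid.astype(np.int64).ravel() * k + p.grid.astype(np.int64).ravel()
        counts += np.bincount(joint, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts=counts, catalog=catalog)


def per_class_metric(conf: ConfusionMatrix, metric_name: str) -> np.ndarray:
    """One metric for every class; NaN where the denominator is zero."""
    tp, fp, fn = conf.tp().astype(float), conf.fp().astype(float), conf.fn().astype(float)
    if metric_name == "IoU":
        num, den = tp, tp + fp + fn
    elif metric_name == "F1":
        num, den = 2 * tp, 2 * tp + fp + fn
    elif metric_name == "PREC":
        num, den = tp, tp + fp
    elif metric_name == "RECALL":
        num, den = tp, tp + fn
    elif metric_name == "CORRECT_PCT":
        return correct_pixel_percentage(conf)
    else:
        raise ValueError(f"unknown metric name {metric_name!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out


def correct_pixel_percentage(conf: ConfusionMatrix) -> np.ndarray:
    """Fraction of each class's ground-truth pixels predicted as that class.

    Diagonal over row sum — identical to per-class recall; undefined (NaN)
    for classes with no ground-truth pixels.
    """
    tp = conf.tp().astype(float)
    row = conf.counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(row > 0, tp / np.where(row > 0, row, 1.0), np.nan)


def metrics_table(
    confusions: Mapping[str, ConfusionMatrix],
    metric_name: str,
    catalog: ClassCatalog,
) -> MetricsTable:
    """Stack per-predictor metric rows into an N×K table, catalog column order."""
    names = tuple(confusions)
    if not names:
        raise ValueError("no confusion matrices supplied")
    values = np.vstack([per_class_metric(confusions[n], metric_name) for n in names])
    return MetricsTable(
        values=values, predictor_names=names, catalog=catalog, metric_name=metric_name
    )


def class_pixel_weights(
    gt: Sequence[LabelMask], catalog: ClassCatalog
) -> ClassPixelWeights:
    """Ground-truth pixel frequency per class over a mask set."""
    if not gt:
        raise ValueError("empty ground-truth mask list")
    k = len(catalog)
    counts = np.zeros(k, dtype=np.int64)
    for mask in gt:
        counts += np.bincount(mask.grid.ravel(), minlength=k)
    return ClassPixelWeights(weights=counts / counts.sum(), catalog=catalog)


def weighted_iou(iou_row: np.ndarray, weights: ClassPixelWeights) -> float:
    """Pixel-frequency-weighted mean of per-class IoU, in [0, 1].

    Every class with positive weight must have a defined IoU (a class present
    in the ground truth always does, since TP+FN > 0 there).
    """
    iou_row = np.asarray(iou_row, dtype=float)
    w = weights.weights
    bad = (w > 0) & np.isnan(iou_row)
    if bad.any():
        names = [weights.catalog.names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"positive-weight classes with undefined IoU: {names}")
    active = w > 0
    return float(np.sum(w[active] * iou_row[active]))
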