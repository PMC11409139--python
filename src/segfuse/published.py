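"""Published MMOTU benchmark figures used as reference input data.

Per-class IoU scores (percent) reported for five DeepLabV3+ variants —
ResNet-18 (CNN1), ResNet-50 (CNN2), InceptionResNet-V2 (CNN3), MobileNet-V2
(CNN4) and Xception (CNN5) — trained on the MMOTU 2-D ovarian-ultrasound
dataset over the 9-class label space, plus the reported weighted-IoU ranking
of the top decision-fusion ensembles against the best individual network.

These numbers are *inputs*: the weight matrix they define drives worked
examples and lets the ensemble-ranking arithmetic be checked without GPU
training runs.
"""

from __future__ import annotations

import numpy as np

from .catalog import ClassCatalog, default_catalog
from .fusion import WeightMatrix

PREDICTOR_NAMES = ("CNN1", "CNN2", "CNN3", "CNN4", "CNN5")

#: Per-class IoU, percent; rows CNN1..CNN5, columns CC SC T TCT SCH NO MC HGSC B.
PUBLISHED_IOU_PCT: tuple[tuple[float, ...], ...] = (
    (86.12, 66.22, 80.79, 53.28, 28.71, 70.19, 46.04, 24.82, 97.89),
    (87.79, 79.01, 83.69, 54.42, 57.75, 75.34, 67.84, 1.91, 98.23),
    (83.68, 65.63, 69.97, 18.82, 12.78, 59.88, 46.38, 1.26, 97.76),
    (71.16, 54.93, 56.71, 4.41, 0.10, 52.24, 26.50, 0.35, 96.79),
    (69.17, 63.03, 61.38, 5.98, 7.13, 58.26, 42.85, 6.21, 97.27),
)

#: Reported top-5 fusion ensembles by weighted IoU (percent), evaluation split.
PUBLISHED_ENSEMBLE_WIOU_PCT: tuple[tuple[tuple[str, ...], float], ...] = (
    (("CNN1", "CNN2", "CNN3"), 91.18),
    (("CNN1", "CNN2"), 88.94),
    (("CNN1", "CNN2", "CNN3", "CNN5"), 88.61),
    (("CNN1", "CNN2", "CNN3", "CNN4", "CNN5"), 88.60),
    (("CNN1", "CNN2", "CNN3", "CNN4"), 86.71),
)

#: Best individual network and its reported weighted IoU (percent).
PUBLISHED_BEST_INDIVIDUAL: tuple[str, float] = ("CNN2", 84.58)


def published_weight_matrix(catalog: ClassCatalog | None = None) -> WeightMatrix:
    """The published per-class IoU table as a fusion weight matrix.

    Percent values are converted to fractions in [0, 1] on ingestion (the
    fused argmax is scale-invariant, but fractions keep one convention).
    """
    catalog = catalog or default_catalog()
    return WeightMatrix(
        weights=np.asarray(PUBLISHED_IOU_PCT, dtype=float) / 100.0,
        predictor_names=PREDICTOR_NAMES,
        catalog=catalog,
        metric_name="IoU",
    )


def top_ensemble_gap_pct() -> float:
    """Weighted-IoU gap (percentage points) between the two best ensembles."""
    scores = sorted((s for _, s in PUBLISHED_ENSEMBLE_WIOU_PCT), reverse=True)
    return round(scores[0] - scores[1], 2)


def n_ensembles_beating_best_individual() -> int:
    """How many listed ensembles exceed the best individual network's score."""
    _, best_single = PUBLISHED_BEST_INDIVIDUAL
    return sum(1 for _, s in PUBLISHED_ENSEMBLE_WIOU_PCT if s > best_single)
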