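"""Per-pixel decision fusion of multiple segmentation predictors.

Each of N predictors emits a hard decision mask; each also carries a per-class
quality weight w(i, j) — by default its per-class IoU measured on a held-out
split. For a pixel where predictor i voted class v_i, the fused score of
class j is::

    score(j) = sum_i  w(i, j) * [v_i == j]

and the fused label is ``argmax_j score(j)``. A predictor therefore counts
for exactly what it has demonstrated on each class: a specialist's vote on
its strong class outweighs several mediocre votes, while its vote carries
little weight on classes it segments poorly.

Two degenerate situations the argmax alone does not settle are resolved by
explicit, deterministic policy:

* **ties** — several classes share the maximal score: the tie policy picks
  the winner (default: lowest class id; a custom class-precedence order can
  be supplied instead);
* **all-zero scores** — every voting predictor has weight 0 for its voted
  class: fall back to a plurality vote over the raw votes, then apply the
  same tie policy.

The vectorized :func:`fuse` is bit-identical to evaluating
:func:`score_pixel` independently at every pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .catalog import ClassCatalog
from .masks import LabelMask
from .metrics import MetricsTable


@dataclass(frozen=True)
class TiePolicy:
    """Deterministic tie resolution via a total precedence order on classes.

    ``precedence`` lists class ids from most to least preferred; among tied
    classes the earliest listed wins. The default (``lowest_id``) is the
    identity order 0, 1, ..., K-1.
    """

    precedence: tuple[int, ...]

    @classmethod
    def lowest_id(cls, catalog: ClassCatalog) -> "TiePolicy":
        return cls(precedence=catalog.class_ids)

    @classmethod
    def from_spec(cls, spec: str, catalog: ClassCatalog) -> "TiePolicy":
        """Parse ``"lowest_id"`` or ``"precedence:NAME,NAME,..."``."""
        if spec == "lowest_id":
            return cls.lowest_id(catalog)
        if spec.startswith("precedence:"):
            names = [s.strip() for s in spec.split(":", 1)[1].split(",")]
            ids = tuple(catalog.id_of(n) for n in names)
            if sorted(ids) != list(catalog.class_ids):
                raise ValueError(
                    f"precedence list must order every catalog class exactly once: {names}"
                )
            return cls(precedence=ids)
        raise ValueError(f"unknown tie policy {spec!r}")

    def rank(self, n_classes: int) -> np.ndarray:
        """rank[class_id] = preference position (0 = most preferred)."""
        if sorted(self.precedence) != list(range(n_classes)):
            raise ValueError("precedence must be a permutation of all class ids")
        rank = np.empty(n_classes, dtype=np.int64)
        rank[list(self.precedence)] = np.arange(n_classes)
        return rank


@dataclass(frozen=True)
class WeightMatrix:
    """N×K per-(predictor, class) vote weights in [0, 1], catalog column order."""

    weights: np.ndarray
    predictor_names: tuple[str, ...]
    catalog: ClassCatalog
    metric_name: str = "IoU"

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        if weights.shape != (len(self.predictor_names), len(self.catalog)):
            raise ValueError(
                f"weights shape {weights.shape} != "
                f"({len(self.predictor_names)}, {len(self.catalog)})"
            )
        if np.isnan(weights).any() or ((weights < 0) | (weights > 1)).any():
            raise ValueError("weights must be finite and lie in [0, 1]")
        if len(set(self.predictor_names)) != len(self.predictor_names):
            raise ValueError("duplicate predictor names")
        object.__setattr__(self, "weights", weights)

    def restrict(self, member_names: Sequence[str]) -> "WeightMatrix":
        """Row-subset for an ensemble's members, preserving the given order."""
        idx = [self.predictor_names.index(n) for n in member_names]
        return WeightMatrix(
            weights=self.weights[idx],
            predictor_names=tuple(member_names),
            catalog=self.catalog,
            metric_name=self.metric_name,
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "predictors": list(self.predictor_names),
                    "classes": list(self.catalog.names),
                    "metric": self.metric_name,
                    "weights": self.weights.tolist(),
                },
                indent=2,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path, catalog: ClassCatalog) -> "WeightMatrix":
        d = json.loads(Path(path).read_text())
        if list(d["classes"]) != list(catalog.names):
            raise ValueError(
                f"weight-matrix class order {d['classes']} != catalog {list(catalog.names)}"
            )
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            predictor_names=tuple(d["predictors"]),
            catalog=catalog,
            metric_name=d.get("metric", "IoU"),
        )


@dataclass(frozen=True)
class DecisionStack:
    """N aligned decision masks (one per predictor) for a single image."""

    decisions: tuple[LabelMask, ...]
    predictor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.decisions) < 1:
            raise ValueError("need at least one decision mask")
        if len(self.decisions) != len(self.predictor_names):
            raise ValueError("decision/name count mismatch")
        shape = self.decisions[0].shape
        for name, d in zip(self.predictor_names, self.decisions):
            if d.shape != shape:
                raise ValueError(f"predictor {name!r} shape {d.shape} != {shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.decisions[0].shape


@dataclass(frozen=True)
class PixelScore:
    """Fused class scores at one pixel, the winning class, and its margin."""

    scores: np.ndarray
    winner: int
    margin: float


@dataclass(frozen=True)
class FusedDecision:
    """Fused mask plus counts of pixels settled by tie policy or fallback."""

    mask: LabelMask
    tie_count: int
    fallback_count: int


def build_weight_matrix(metrics: MetricsTable) -> WeightMatrix:
    """Adopt a per-class performance table as the fusion weight matrix.

    IoU is the default weighting metric, but any per-class metric table is
    accepted so other quality measures can drive the fusion. Undefined (NaN)
    cells become weight 0: a predictor never evaluated on a class gets no say
    in it.
    """
    if len(metrics.predictor_names) == 0:
        raise ValueError("empty metrics table")
    return WeightMatrix(
        weights=np.nan_to_num(metrics.values, nan=0.0),
        predictor_names=metrics.predictor_names,
        catalog=metrics.catalog,
        metric_name=metrics.metric_name,
    )


def _pick(rank: np.ndarray, scores: np.ndarray) -> int:
    """Argmax over scores, ties resolved by lowest precedence rank."""
    best = scores.max()
    tied = np.flatnonzero(scores == best)
    return int(tied[np.argmin(rank[tied])])


def score_pixel(
    weights: WeightMatrix,
    votes: Sequence[int],
    tie_policy: TiePolicy | None = None,
) -> PixelScore:
    """Fuse one pixel's N votes into per-class scores and a winning class.

    This is the defining pixelwise contract; :func:`fuse` must agree with it
    bit-for-bit at every pixel.
    """
    k = len(weights.catalog)
    if len(votes) != len(weights.predictor_names):
        raise ValueError(
            f"got {len(votes)} votes for {len(weights.predictor_names)} predictors"
        )
    tie_policy = tie_policy or TiePolicy.lowest_id(weights.catalog)
    rank = tie_policy.rank(k)
    scores = np.zeros(k, dtype=float)
    for i, v in enumerate(votes):
        v = int(v)
        if v not in weights.catalog.class_ids:
            raise ValueError(f"vote {v} outside catalog")
        scores[v] += weights.weights[i, v]
    if scores.max() > 0:
        winner = _pick(rank, scores)
    else:
        counts = np.bincount([int(v) for v in votes], minlength=k).astype(float)
        winner = _pick(rank, counts)
    others = np.delete(scores, winner)
    margin = float(scores[winner] - (others.max() if others.size else 0.0))
    return PixelScore(scores=scores, winner=winner, margin=margin)


def fuse(
    stack: DecisionStack,
    weights: WeightMatrix,
    tie_policy: TiePolicy | None = None,
) -> FusedDecision:
    """Fuse an aligned stack of decision masks into one mask (vectorized).

    Requires the stack's predictor order to match the weight-matrix row
    order. Tie and fallback counts report how many pixels were settled by
    the tie policy and the all-zero-score plurality fallback respectively.
    """
    if stack.predictor_names != weights.predictor_names:
        raise ValueError(
            f"predictor order mismatch: stack {stack.predictor_names} "
            f"vs weights {weights.predictor_names}"
        )
    catalog = weights.catalog
    k = len(catalog)
    tie_policy = tie_policy or TiePolicy.lowest_id(catalog)
    rank = tie_policy.rank(k)
    h, w = stack.shape
    n_pix = h * w
    scores = np.zeros((n_pix, k), dtype=float)
    vote_counts = np.zeros((n_pix, k), dtype=np.int64)
    pix = np.arange(n_pix)
    for i, decision in enumerate(stack.decisions):
        v = decision.grid.ravel().astype(np.int64)
        scores[pix, v] += weights.weights[i, v]
        vote_counts[pix, v] += 1
    max_score = scores.max(axis=1)
    fallback = max_score <= 0.0
    # precedence-ordered argmax: reorder columns so np.argmax's first-max
    # rule realises the tie policy, then map back to class ids
    order = np.asarray(tie_policy.precedence, dtype=np.int64)
    winner = order[np.argmax(scores[:, order], axis=1)]
    score_ties = (scores == max_score[:, None]).sum(axis=1) > 1
    if fallback.any():
        counts_fb = vote_counts[fallback]
        winner[fallback] = order[np.argmax(counts_fb[:, order], axis=1)]
        fb_ties = (counts_fb == counts_fb.max(axis=1)[:, None]).sum(axis=1) > 1
        tie_count = int(score_ties[~fallback].sum()) + int(fb_ties.sum())
    else:
        tie_count = int(score_ties.sum())
    mask = LabelMask(grid=winner.reshape(h, w).astype(np.uint8), catalog=catalog)
    return FusedDecision(mask=mask, tie_count=tie_count, fallback_count=int(fallback.sum()))
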