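"""Model/Results front-end for decision-fusion ensemble selection.

:class:`DecisionFusionEnsemble` is built from data — aligned ground-truth and
per-predictor decision masks — and ``fit()`` estimates the per-class IoU
weight matrix, evaluates every ensemble subset and returns an
:class:`EnsembleSearchResults` carrying the selected ensemble, the full
ranking, per-class diagnostics and a ``summary()`` table. ``predict()`` on
the results fuses new decision stacks with the fitted weights.

Typical use::

    model = DecisionFusionEnsemble.from_study("study_dir/")
    res = model.fit()
    print(res.summary())
    fused = res.predict({"CNN1": mask1, "CNN2": mask2, ...})
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import ClassCatalog
from .dataset import MaskSet, load_study
from .fusion import DecisionStack, TiePolicy, WeightMatrix, build_weight_matrix, fuse
from .masks import LabelMask
from .metrics import accumulate_confusion, class_pixel_weights, metrics_table, weighted_iou
from .search import SearchReport, run_search


class DecisionFusionEnsemble:
    """Ensemble-selection model over hard segmentation decisions.

    Parameters
    ----------
    gt, predictions
        Evaluation-split ground truth by image id and decision masks by
        predictor name by image id.
    weight_gt, weight_predictions
        Optional separate split used to estimate the weight matrix. When
        omitted the evaluation split doubles as the weight-fitting split —
        convenient, but weights fitted on the data they rank are
        optimistically biased; pass a held-out split for honest selection.
    weight_metric
        Per-class metric adopted as vote weights (default ``"IoU"``).
    tie_policy
        Tie resolution for the fused argmax (default lowest class id).
    """

    def __init__(
        self,
        gt: Mapping[str, LabelMask],
        predictions: Mapping[str, Mapping[str, LabelMask]],
        catalog: ClassCatalog,
        weight_metric: str = "IoU",
        tie_policy: TiePolicy | None = None,
        weight_gt: Mapping[str, LabelMask] | None = None,
        weight_predictions: Mapping[str, Mapping[str, LabelMask]] | None = None,
    ) -> None:
        if len(predictions) < 2:
            raise ValueError("ensemble selection needs at least 2 predictors")
        self.gt = dict(gt)
        self.predictions = {k: dict(v) for k, v in predictions.items()}
        self.catalog = catalog
        self.weight_metric = weight_metric
        self.tie_policy = tie_policy or TiePolicy.lowest_id(catalog)
        self.weight_gt = dict(weight_gt) if weight_gt is not None else self.gt
        self.weight_predictions = (
            {k: dict(v) for k, v in weight_predictions.items()}
            if weight_predictions is not None
            else self.predictions
        )

    @classmethod
    def from_study(
        cls,
        root: str | Path,
        catalog: ClassCatalog | None = None,
        image_ids: Sequence[str] | None = None,
        **kwargs,
    ) -> "DecisionFusionEnsemble":
        """Build the model from an on-disk study layout (gt/, predictions/)."""
        gt, predictions = load_study(root, catalog)
        if catalog is None:
            catalog = next(iter(gt.values())).catalog
        if image_ids is not None:
            ids = set(image_ids)
            gt = {i: m for i, m in gt.items() if i in ids}
            predictions = {
                n: {i: m for i, m in masks.items() if i in ids}
                for n, masks in predictions.items()
            }
        return cls(gt=gt, predictions=predictions, catalog=catalog, **kwargs)

    def estimate_weights(self) -> WeightMatrix:
        """Per-predictor, per-class metric table on the weight-fitting split."""
        gt_list = [self.weight_gt[i] for i in sorted(self.weight_gt)]
        confusions = {
            name: accumulate_confusion(
                gt_list, [masks[i] for i in sorted(self.weight_gt)], self.catalog
            )
            for name, masks in self.weight_predictions.items()
        }
        table = metrics_table(confusions, self.weight_metric, self.catalog)
        return build_weight_matrix(table)

    def fit(
        self, min_size: int = 2, include_individuals: bool = True
    ) -> "EnsembleSearchResults":
        """Estimate weights, search all subsets, and package the results."""
        weights = self.estimate_weights()
        report = run_search(
            self.gt,
            self.predictions,
            weights,
            min_size=min_size,
            include_individuals=include_individuals,
            tie_policy=self.tie_policy,
        )
        return EnsembleSearchResults(model=self, weight_matrix=weights, report=report)


@dataclass
class EnsembleSearchResults:
    """Fitted weights, the exhaustive subset ranking, and the selected ensemble."""

    model: DecisionFusionEnsemble
    weight_matrix: WeightMatrix
    report: SearchReport

    @property
    def best_members(self) -> tuple[str, ...]:
        return self.report.best.member_names

    @property
    def best_weighted_iou(self) -> float:
        return self.report.best_row().weighted_iou

    @property
    def ranking(self) -> pd.DataFrame:
        return self.report.to_frame()

    def individual_weighted_iou(self) -> dict[str, float]:
        return {
            r.spec.member_names[0]: r.weighted_iou
            for r in self.report.individual_rows()
        }

    def improvement_over_best_individual(self) -> float:
        """Best ensemble weighted IoU minus best individual weighted IoU."""
        individuals = self.individual_weighted_iou()
        if not individuals:
            raise ValueError("fit with include_individuals=True to compare")
        return self.best_weighted_iou - max(individuals.values())

    def predict(
        self, decisions: Mapping[str, LabelMask], members: Sequence[str] | None = None
    ) -> LabelMask:
        """Fuse one image's decision masks with the fitted weights.

        Uses the selected best ensemble's members unless ``members`` is given.
        """
        members = tuple(members) if members is not None else self.best_members
        stack = DecisionStack(
            decisions=tuple(decisions[n] for n in members), predictor_names=members
        )
        return fuse(stack, self.weight_matrix.restrict(members), self.model.tie_policy).mask

    def summary(self, top: int = 10) -> str:
        """Human-readable report: selected ensemble and the top of the ranking."""
        frame = self.ranking.head(top)
        lines = [
            "Decision-fusion ensemble selection",
            "=" * 50,
            f"Predictors:     {', '.join(self.weight_matrix.predictor_names)}",
            f"Classes:        {', '.join(self.model.catalog.names)}",
            f"Weight metric:  {self.weight_matrix.metric_name}",
            f"Images:         {len(self.model.gt)}",
            f"Selected:       {self.report.best.label}",
            f"Weighted IoU:   {self.best_weighted_iou:.4f}",
        ]
        individuals = self.individual_weighted_iou()
        if individuals:
            best_single = max(individuals, key=individuals.get)
            lines.append(
                f"Best single:    {best_single} ({individuals[best_single]:.4f})"
            )
            lines.append(
                f"Improvement:    {self.improvement_over_best_individual():+.4f}"
            )
        lines.append("-" * 50)
        cols = ["rank", "ensemble", "kind", "weighted_iou"]
        lines.append(frame[cols].to_string(index=False))
        return "\n".join(lines)

    def plot_ranking(self, top: int = 10, ax=None):
        """Horizontal bar chart of the top-ranked subsets' weighted IoU."""
        import matplotlib.pyplot as plt

        frame = self.ranking.head(top).iloc[::-1]
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.45 * len(frame) + 1))
        colors = [
            "tab:blue" if k == "ensemble" else "tab:gray" for k in frame["kind"]
        ]
        ax.barh(frame["ensemble"], frame["weighted_iou"], color=colors)
        ax.set_xlabel("weighted IoU")
        ax.set_xlim(0, 1)
        ax.set_title("Ensemble ranking")
        return ax
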