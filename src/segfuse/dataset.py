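"""Dataset plumbing: raw-layout adaptation, stratified splitting, study I/O.

Two on-disk layouts are understood:

* **Raw layout** — how ultrasound mask datasets typically ship:
  ``images/<id>.<ext>`` grayscale scans, ``binary_masks/<id>.png`` with pixel
  values {0, 1}, and ``metadata.csv`` (columns ``image_id,class_name``) mapping
  each image to its tumor class. :func:`adapt_dataset` lifts this into the
  multi-class study layout.

* **Study layout** — what evaluation and fusion consume:
  ``gt/<id>.png`` multi-class label masks, ``predictions/<name>/<id>.png`` one
  directory of decision masks per predictor, and ``catalog.json``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalog import ClassCatalog
from .masks import LabelMask, adapt_binary_mask, read_mask, resize_mask, write_mask

MaskSet = dict[str, LabelMask]


@dataclass(frozen=True)
class ImageRecord:
    """One raw dataset image: id, file paths, and metadata-assigned class."""

    image_id: str
    image_path: Path
    mask_path: Path
    tumor_class: int


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/val/test id lists forming a partition of the dataset."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fractions: tuple[float, float, float]
    seed: int

    def __post_init__(self) -> None:
        all_ids = list(self.train_ids) + list(self.val_ids) + list(self.test_ids)
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split id lists overlap")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "train": list(self.train_ids),
                    "val": list(self.val_ids),
                    "test": list(self.test_ids),
                    "fractions": list(self.fractions),
                    "seed": self.seed,
                },
                indent=2,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetSplit":
        d = json.loads(Path(path).read_text())
        return cls(
            train_ids=tuple(d["train"]),
            val_ids=tuple(d["val"]),
            test_ids=tuple(d["test"]),
            fractions=tuple(d["fractions"]),
            seed=int(d["seed"]),
        )


def read_metadata(path: str | Path, catalog: ClassCatalog) -> dict[str, int]:
    """Read ``metadata.csv`` (image_id,class_name) into an id → class-id map."""
    mapping: dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            mapping[row["image_id"]] = catalog.id_of(row["class_name"])
    return mapping


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Allocate n items over fractions; each count is within 1 of n*fraction.

    Integer parts first; leftover units go to the largest fractional
    remainders, ties broken by position (train before val before test).
    """
    exact = [n * f for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    leftover = n - sum(base)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(exact[i] - base[i]), i)
    )
    for i in remainders[:leftover]:
        base[i] += 1
    return base


def split_dataset(
    records: Sequence[ImageRecord],
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Stratified train/val/test split, balanced per tumor class.

    Within each tumor class (iterated in class-id order) the ids are shuffled
    with a seeded RNG and allocated to the three splits by largest-remainder
    rounding, so each split's per-class count deviates from
    fraction × class-total by at most 1. Deterministic for a fixed seed.
    """
    if not records:
        raise ValueError("no records to split")
    if any(f < 0 for f in fractions):
        raise ValueError(f"fractions must be non-negative, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    by_class: dict[int, list[ImageRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.tumor_class, []).append(rec)
    rng = np.random.default_rng(seed)
    buckets: tuple[list[str], list[str], list[str]] = ([], [], [])
    for cls in sorted(by_class):
        ids = sorted(r.image_id for r in by_class[cls])
        rng.shuffle(ids)
        n_train, n_val, _ = _largest_remainder(len(ids), fractions)
        buckets[0].extend(ids[:n_train])
        buckets[1].extend(ids[n_train : n_train + n_val])
        buckets[2].extend(ids[n_train + n_val :])
    return DatasetSplit(
        train_ids=tuple(buckets[0]),
        val_ids=tuple(buckets[1]),
        test_ids=tuple(buckets[2]),
        fractions=tuple(fractions),
        seed=seed,
    )


def adapt_dataset(
    images_dir: str | Path,
    binary_masks_dir: str | Path,
    metadata_path: str | Path,
    out_dir: str | Path,
    catalog: ClassCatalog,
    target_size: tuple[int, int] | None = (900, 600),
) -> list[ImageRecord]:
    """Lift a raw binary-mask dataset into the multi-class study layout.

    Each binary mask is resized (nearest-neighbor) to ``target_size``
    (width, height) and its 1-pixels are relabeled with the class the metadata
    file assigns to that image. Writes ``gt/<id>.png`` and ``catalog.json``
    under ``out_dir`` and returns the records processed.
    """
    images_dir, binary_masks_dir = Path(images_dir), Path(binary_masks_dir)
    out_dir = Path(out_dir)
    mapping = read_metadata(metadata_path, catalog)
    gt_dir = out_dir / "gt"
    gt_dir.mkdir(parents=True, exist_ok=True)
    # binary masks live in a permissive 0/1 space until relabeled
    binary_catalog = ClassCatalog.from_names(["bg", "fg"], background="bg")
    records: list[ImageRecord] = []
    for image_id in sorted(mapping):
        mask_path = binary_masks_dir / f"{image_id}.png"
        image_path = _find_image(images_dir, image_id)
        binary = read_mask(mask_path, binary_catalog)
        if target_size is not None:
            width, height = target_size
            binary = resize_mask(binary, height, width)
        adapted = adapt_binary_mask(binary, mapping[image_id], catalog)
        write_mask(adapted, gt_dir / f"{image_id}.png")
        records.append(
            ImageRecord(
                image_id=image_id,
                image_path=image_path,
                mask_path=mask_path,
                tumor_class=mapping[image_id],
            )
        )
    catalog.to_json(out_dir / "catalog.json")
    return records


def _find_image(images_dir: Path, image_id: str) -> Path:
    for ext in (".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"):
        cand = images_dir / f"{image_id}{ext}"
        if cand.exists():
            return cand
    return images_dir / f"{image_id}.png"  # images are optional for mask-only studies


def save_study(
    root: str | Path,
    gt: Mapping[str, LabelMask],
    predictions: Mapping[str, Mapping[str, LabelMask]],
    catalog: ClassCatalog,
) -> Path:
    """Write ground truth and per-predictor decision masks in the study layout."""
    root = Path(root)
    gt_dir = root / "gt"
    gt_dir.mkdir(parents=True, exist_ok=True)
    for image_id, mask in gt.items():
        write_mask(mask, gt_dir / f"{image_id}.png")
    for name, masks in predictions.items():
        pred_dir = root / "predictions" / name
        pred_dir.mkdir(parents=True, exist_ok=True)
        for image_id, mask in masks.items():
            write_mask(mask, pred_dir / f"{image_id}.png")
    catalog.to_json(root / "catalog.json")
    return root


def load_study(
    root: str | Path, catalog: ClassCatalog | None = None
) -> tuple[MaskSet, dict[str, MaskSet]]:
    """Load a study directory into aligned ground-truth and prediction sets.

    Validates that every predictor covers exactly the ground-truth image ids
    and that every prediction matches its ground truth's dimensions; errors
    name the offending predictor and image id.
    """
    root = Path(root)
    if catalog is None:
        catalog = ClassCatalog.from_json(root / "catalog.json")
    gt_dir = root / "gt"
    if not gt_dir.is_dir():
        raise FileNotFoundError(f"study has no gt/ directory: {root}")
    gt = {p.stem: read_mask(p, catalog) for p in sorted(gt_dir.glob("*.png"))}
    if not gt:
        raise ValueError(f"study has no ground-truth masks: {gt_dir}")
    predictions: dict[str, MaskSet] = {}
    pred_root = root / "predictions"
    pred_dirs = sorted(p for p in pred_root.iterdir() if p.is_dir()) if pred_root.is_dir() else []
    for pred_dir in pred_dirs:
        name = pred_dir.name
        masks = {p.stem: read_mask(p, catalog) for p in sorted(pred_dir.glob("*.png"))}
        missing = set(gt) - set(masks)
        extra = set(masks) - set(gt)
        if missing or extra:
            raise ValueError(
                f"predictor {name!r} image ids misaligned with ground truth: "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        for image_id, mask in masks.items():
            if mask.shape != gt[image_id].shape:
                raise ValueError(
                    f"predictor {name!r}, image {image_id!r}: prediction shape "
                    f"{mask.shape} != ground truth shape {gt[image_id].shape}"
                )
        predictions[name] = masks
    return gt, predictions
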