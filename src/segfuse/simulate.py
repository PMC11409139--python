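"""Synthetic ultrasound-style studies: lesion masks plus simulated predictors.

Training five segmentation networks on a clinical ultrasound dataset needs
GPUs and data access; exercising the fusion and search machinery does not.
This module generates ground-truth masks — elliptical lesions of sampled
tumor classes on a background frame, echoing the one-lesion-per-image
structure of annotated ovarian scans — and simulates predictors whose error
structure is controlled by a per-class row-stochastic confusion profile Q
plus optional boundary jitter.

The noise model is per-pixel independent label noise after jitter. Real
network errors are spatially correlated; independence is chosen deliberately
because it admits closed-form expectations (the empirical confusion of a
simulated predictor converges to its Q), which makes every fusion and search
contract testable.

Randomness is derived from one root seed with fixed per-stream indices
(ground truth / jitter / labels, keyed by image index), so adding a predictor
never perturbs previously generated streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .catalog import ClassCatalog, default_catalog
from .dataset import MaskSet, save_study
from .masks import LabelMask

# stream tags keeping ground-truth, jitter and label-noise draws independent
_GT_STREAM, _JITTER_STREAM, _LABEL_STREAM = 0, 1, 2


@dataclass(frozen=True)
class SceneSpec:
    """Scene geometry and class mix for synthetic ground truth.

    Defaults give 300×200 frames (the 3:2 aspect of 900×600 adapted scans at
    a ninth of the pixel count), one elliptical lesion per image with
    semi-axes 20–60 px, and a uniform class mix over the 8 tumor classes.
    """

    height: int = 200
    width: int = 300
    lesions_per_image: tuple[int, int] = (1, 1)
    semi_axis_range: tuple[int, int] = (20, 60)
    class_frequencies: tuple[float, ...] | None = None
    seed: int = 0
    catalog: ClassCatalog = field(default_factory=default_catalog)

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("frame dimensions must be positive")
        lo, hi = self.semi_axis_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad semi-axis range {self.semi_axis_range}")
        if hi * 2 >= min(self.height, self.width):
            raise ValueError(
                f"lesion semi-axis {hi} too large for {self.height}x{self.width} frame"
            )
        freqs = self.class_frequencies
        if freqs is not None:
            if len(freqs) != len(self.catalog.tumor_ids):
                raise ValueError(
                    f"need {len(self.catalog.tumor_ids)} class frequencies, got {len(freqs)}"
                )
            if any(f < 0 for f in freqs) or sum(freqs) <= 0:
                raise ValueError("class frequencies must be non-negative, not all zero")

    def tumor_probs(self) -> np.ndarray:
        freqs = self.class_frequencies
        if freqs is None:
            freqs = tuple(1.0 for _ in self.catalog.tumor_ids)
        p = np.asarray(freqs, dtype=float)
        return p / p.sum()


@dataclass(frozen=True)
class PredictorProfile:
    """A simulated predictor's error structure.

    ``confusion`` is a K×K row-stochastic matrix Q: row = true class, column =
    emitted class, so Q[c, c] is the predictor's per-pixel accuracy on class c.
    ``boundary_jitter`` grows or shrinks lesion regions by up to that many
    pixels before label noise, mimicking contour disagreement.
    """

    name: str
    confusion: np.ndarray
    boundary_jitter: int = 0

    def __post_init__(self) -> None:
        q = np.asarray(self.confusion, dtype=float)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise ValueError(f"confusion must be square, got {q.shape}")
        if (q < 0).any():
            raise ValueError("confusion entries must be non-negative")
        if not np.allclose(q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion rows must each sum to 1")
        if self.boundary_jitter < 0:
            raise ValueError("boundary_jitter must be >= 0")
        object.__setattr__(self, "confusion", q)


@dataclass(frozen=True)
class SyntheticStudy:
    """Generated ground truth + per-predictor decisions + the true profiles."""

    gt: MaskSet
    predictions: dict[str, MaskSet]
    profiles: tuple[PredictorProfile, ...]
    catalog: ClassCatalog
    seed: int

    def write(self, root: str | Path) -> Path:
        """Write the study layout plus ``profiles.json`` for later verification."""
        root = Path(root)
        save_study(root, self.gt, self.predictions, self.catalog)
        payload = {
            "seed": self.seed,
            "profiles": [
                {
                    "name": p.name,
                    "confusion": p.confusion.tolist(),
                    "boundary_jitter": p.boundary_jitter,
                }
                for p in self.profiles
            ],
        }
        (root / "profiles.json").write_text(json.dumps(payload, indent=2))
        return root


def _image_ids(n_images: int) -> list[str]:
    return [f"img{i:04d}" for i in range(n_images)]


def generate_ground_truth(spec: SceneSpec, n_images: int) -> MaskSet:
    """Sample n_images lesion masks: background plus seeded elliptical lesions."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    probs = spec.tumor_probs()
    tumor_ids = np.asarray(spec.catalog.tumor_ids)
    lo, hi = spec.semi_axis_range
    masks: MaskSet = {}
    for idx, image_id in enumerate(_image_ids(n_images)):
        rng = np.random.default_rng([spec.seed, _GT_STREAM, idx])
        grid = np.full(
            (spec.height, spec.width), spec.catalog.background_id, dtype=np.uint8
        )
        n_lesions = int(rng.integers(spec.lesions_per_image[0], spec.lesions_per_image[1] + 1))
        for _ in range(n_lesions):
            cls = int(rng.choice(tumor_ids, p=probs))
            a = int(rng.integers(lo, hi + 1))
            b = int(rng.integers(lo, hi + 1))
            margin_r, margin_c = max(a, b), max(a, b)
            cy = int(rng.integers(margin_r, spec.height - margin_r))
            cx = int(rng.integers(margin_c, spec.width - margin_c))
            angle = float(rng.uniform(0, np.pi))
            rr, cc = draw_ellipse(
                cy, cx, a, b, shape=grid.shape, rotation=angle
            )
            grid[rr, cc] = cls
        masks[image_id] = LabelMask(grid=grid, catalog=spec.catalog)
    return masks


def _jitter_regions(
    grid: np.ndarray, catalog: ClassCatalog, radius: int, rng: np.random.Generator
) -> np.ndarray:
    """Grow or shrink each lesion class region by a sampled amount ≤ radius."""
    out = np.full_like(grid, catalog.background_id)
    struct = ndimage.generate_binary_structure(2, 2)
    for cls in catalog.tumor_ids:
        region = grid == cls
        if not region.any():
            continue
        amount = int(rng.integers(-radius, radius + 1))
        if amount > 0:
            region = ndimage.binary_dilation(region, struct, iterations=amount)
        elif amount < 0:
            region = ndimage.binary_erosion(region, struct, iterations=-amount)
        out[region] = cls
    return out


def simulate_predictor(
    gt: Mapping[str, LabelMask], profile: PredictorProfile, seed: int
) -> MaskSet:
    """Corrupt ground truth through a predictor profile, deterministically.

    Per image: optional boundary jitter of lesion regions, then each pixel's
    emitted label drawn independently from the Q row of its (jittered) true
    label. Streams are keyed by (seed, image index, stream tag).
    """
    first = next(iter(gt.values()))
    catalog = first.catalog
    k = len(catalog)
    if profile.confusion.shape != (k, k):
        raise ValueError(
            f"profile confusion is {profile.confusion.shape}, catalog has {k} classes"
        )
    q = profile.confusion
    out: MaskSet = {}
    for idx, image_id in enumerate(sorted(gt)):
        grid = gt[image_id].grid
        if profile.boundary_jitter > 0:
            jrng = np.random.default_rng([seed, idx, _JITTER_STREAM])
            grid = _jitter_regions(grid, catalog, profile.boundary_jitter, jrng)
        lrng = np.random.default_rng([seed, idx, _LABEL_STREAM])
        emitted = np.empty_like(grid)
        for cls in range(k):
            sel = grid == cls
            n = int(sel.sum())
            if n == 0:
                continue
            emitted[sel] = lrng.choice(k, size=n, p=q[cls]).astype(grid.dtype)
        out[image_id] = LabelMask(grid=emitted, catalog=catalog)
    return out


def make_study(
    spec: SceneSpec,
    profiles: Sequence[PredictorProfile],
    n_images: int,
) -> SyntheticStudy:
    """Generate ground truth and one simulated prediction set per profile.

    Predictor streams are keyed by (root seed, predictor index), so appending
    a profile leaves existing ground truth and predictions untouched.
    """
    if not profiles:
        raise ValueError("need at least one predictor profile")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate profile names: {names}")
    gt = generate_ground_truth(spec, n_images)
    predictions = {
        p.name: simulate_predictor(gt, p, seed=int(np.random.default_rng(
            [spec.seed, 1000 + i]).integers(2**31)))
        for i, p in enumerate(profiles)
    }
    return SyntheticStudy(
        gt=gt,
        predictions=predictions,
        profiles=tuple(profiles),
        catalog=spec.catalog,
        seed=spec.seed,
    )


def specialist_profile(
    name: str,
    catalog: ClassCatalog,
    strong_classes: Sequence[int],
    strong_accuracy: float = 0.95,
    weak_accuracy: float = 0.35,
    background_accuracy: float = 0.98,
    boundary_jitter: int = 0,
) -> PredictorProfile:
    """A predictor that excels on ``strong_classes`` and is poor elsewhere.

    Off-diagonal mass goes to the background class (missed lesion pixels) —
    the dominant failure mode of real lesion segmenters — except for the
    background row, whose errors are spread uniformly over lesion classes
    (false lesion speckle).
    """
    k = len(catalog)
    bg = catalog.background_id
    q = np.zeros((k, k))
    for cls in catalog.tumor_ids:
        acc = strong_accuracy if cls in strong_classes else weak_accuracy
        q[cls, cls] = acc
        q[cls, bg] = 1.0 - acc
    q[bg, bg] = background_accuracy
    spread = (1.0 - background_accuracy) / len(catalog.tumor_ids)
    for cls in catalog.tumor_ids:
        q[bg, cls] = spread
    return PredictorProfile(name=name, confusion=q, boundary_jitter=boundary_jitter)
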