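"""Label masks: the per-pixel class-id grids that segmentation operates on.

A :class:`LabelMask` wraps a 2-D integer grid whose cells are class ids from a
governing :class:`~segfuse.catalog.ClassCatalog` — it represents both ground
truth annotations and each predictor's per-pixel decision matrix. Masks are
stored on disk as single-channel 8-bit PNGs with the id as the pixel value,
which round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .catalog import ClassCatalog


class ForeignLabelError(ValueError):
    """A mask contains a pixel value that is not a catalog class id."""

    def __init__(self, value: int, row: int, col: int, source: str = ""):
        self.value = int(value)
        self.row = int(row)
        self.col = int(col)
        where = f" in {source}" if source else ""
        super().__init__(
            f"foreign label {value} at pixel (row={row}, col={col}){where}"
        )


@dataclass(frozen=True)
class LabelMask:
    """2-D grid of class ids (row = image y, col = image x)."""

    grid: np.ndarray
    catalog: ClassCatalog

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2 or grid.shape[0] < 1 or grid.shape[1] < 1:
            raise ValueError(f"mask grid must be 2-D and non-empty, got shape {grid.shape}")
        if not np.issubdtype(grid.dtype, np.integer):
            raise ValueError(f"mask grid must be integer-typed, got {grid.dtype}")
        _check_labels(grid, self.catalog)
        object.__setattr__(self, "grid", grid)

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def labels_present(self) -> set[int]:
        return set(np.unique(self.grid).tolist())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelMask):
            return NotImplemented
        return self.catalog == other.catalog and np.array_equal(self.grid, other.grid)


def _check_labels(grid: np.ndarray, catalog: ClassCatalog, source: str = "") -> None:
    valid = np.zeros(256, dtype=bool)
    valid[list(catalog.class_ids)] = True
    flat = grid.ravel()
    bad = ~valid[flat] if grid.dtype == np.uint8 else ~np.isin(flat, catalog.class_ids)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        r, c = divmod(idx, grid.shape[1])
        raise ForeignLabelError(int(flat[idx]), r, c, source)


def read_mask(path: str | Path, catalog: ClassCatalog) -> LabelMask:
    """Read a single-channel PNG of class ids into a :class:`LabelMask`.

    Raises ``FileNotFoundError`` for a missing file and
    :class:`ForeignLabelError` if any pixel value is outside the catalog.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    with Image.open(path) as im:
        if im.mode not in ("L", "P", "I", "I;16"):
            raise ValueError(
                f"{path}: expected a single-channel label image, got mode {im.mode!r}"
            )
        grid = np.asarray(im.convert("I") if im.mode == "I;16" else im, dtype=np.int64)
    _check_labels(grid, catalog, source=str(path))
    return LabelMask(grid=grid.astype(np.uint8), catalog=catalog)


def write_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a mask as a lossless single-channel 8-bit PNG; inverse of read_mask."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    Image.fromarray(mask.grid.astype(np.uint8), mode="L").save(path, format="PNG")
    return path


def adapt_binary_mask(
    binary: LabelMask, tumor_class: int, catalog: ClassCatalog
) -> LabelMask:
    """Lift a raw {0, 1} lesion mask into the multi-class label space.

    Raw dataset masks are binary: 0 is background, 1 marks the lesion, and the
    lesion's class is only known from the per-image metadata. This maps 0 to
    the catalog background id and 1 to ``tumor_class``.
    """
    if tumor_class == catalog.background_id:
        raise ValueError("tumor_class must not be the background class")
    if tumor_class not in catalog.class_ids:
        raise ValueError(f"tumor_class {tumor_class} not in catalog")
    grid = np.asarray(binary.grid)
    extra = set(np.unique(grid).tolist()) - {0, 1}
    if extra:
        raise ValueError(f"binary mask contains non-binary values: {sorted(extra)}")
    out = np.where(grid == 1, np.uint8(tumor_class), np.uint8(catalog.background_id))
    return LabelMask(grid=out, catalog=catalog)


def resize_mask(mask: LabelMask, target_height: int, target_width: int) -> LabelMask:
    """Nearest-neighbor resample of a label mask to the target dimensions.

    Target pixel (r, c) copies source pixel (r*H//H', c*W//W'). Averaging
    interpolation would blend ids into labels that exist nowhere in the input,
    so only nearest-neighbor is offered; the output label set is always a
    subset of the input label set.
    """
    if target_height < 1 or target_width < 1:
        raise ValueError(
            f"target dimensions must be >= 1, got {target_height}x{target_width}"
        )
    h, w = mask.shape
    rows = (np.arange(target_height, dtype=np.int64) * h) // target_height
    cols = (np.arange(target_width, dtype=np.int64) * w) // target_width
    return LabelMask(grid=mask.grid[np.ix_(rows, cols)], catalog=mask.catalog)
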