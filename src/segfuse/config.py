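"""Run configuration: one human-readable YAML file, validated and defaulted.

CLI flags override config values, which override the documented defaults
(weight metric ``IoU``, tie policy ``lowest_id``, resize target 900×600,
seed 0). Enumerated values are checked here so a typo fails at validation
time, not mid-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .catalog import ClassCatalog, default_catalog
from .fusion import TiePolicy
from .metrics import METRIC_NAMES

DEFAULT_SEED = 0
DEFAULT_SIZE = (900, 600)  # width, height


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration for a pipeline run."""

    catalog_path: Path | None = None
    study_root: Path | None = None
    split_manifest: Path | None = None
    weight_metric: str = "IoU"
    tie_policy: str = "lowest_id"
    resize_target: tuple[int, int] = DEFAULT_SIZE
    seed: int = DEFAULT_SEED
    out_dir: Path | None = None

    def load_catalog(self) -> ClassCatalog:
        if self.catalog_path is not None:
            return ClassCatalog.from_json(self.catalog_path)
        if self.study_root is not None and (self.study_root / "catalog.json").exists():
            return ClassCatalog.from_json(self.study_root / "catalog.json")
        return default_catalog()

    def load_tie_policy(self, catalog: ClassCatalog) -> TiePolicy:
        return TiePolicy.from_spec(self.tie_policy, catalog)


def parse_size(text: str) -> tuple[int, int]:
    """Parse ``"900x600"`` (width x height)."""
    try:
        w, h = (int(p) for p in text.lower().split("x"))
    except ValueError:
        raise ValueError(f"size must look like 900x600, got {text!r}") from None
    if w < 1 or h < 1:
        raise ValueError(f"size must be positive, got {text!r}")
    return (w, h)


def validate_config(path: str | Path) -> RunConfig:
    """Load, default, and validate a YAML run configuration."""
    path = Path(path)
    raw: dict[str, Any] = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {
        "catalog",
        "study",
        "split_manifest",
        "weight_metric",
        "tie_policy",
        "size",
        "seed",
        "out_dir",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")

    def _path(key: str, must_exist: bool) -> Path | None:
        if key not in raw or raw[key] is None:
            return None
        p = Path(raw[key])
        if not p.is_absolute():
            p = path.parent / p
        if must_exist and not p.exists():
            raise FileNotFoundError(f"{path}: {key} path does not exist: {p}")
        return p

    metric = raw.get("weight_metric", "IoU")
    if metric not in METRIC_NAMES:
        raise ValueError(
            f"{path}: unknown weight_metric {metric!r}; choose from {METRIC_NAMES}"
        )
    tie_policy = raw.get("tie_policy", "lowest_id")
    if tie_policy != "lowest_id" and not str(tie_policy).startswith("precedence:"):
        raise ValueError(
            f"{path}: unknown tie_policy {tie_policy!r}; "
            "use 'lowest_id' or 'precedence:NAME,NAME,...'"
        )
    size = raw.get("size")
    resize_target = parse_size(size) if isinstance(size, str) else tuple(size) if size else DEFAULT_SIZE
    seed = int(raw.get("seed", DEFAULT_SEED))
    cfg = RunConfig(
        catalog_path=_path("catalog", must_exist=True),
        study_root=_path("study", must_exist=True),
        split_manifest=_path("split_manifest", must_exist=True),
        weight_metric=metric,
        tie_policy=str(tie_policy),
        resize_target=resize_target,
        seed=seed,
        out_dir=_path("out_dir", must_exist=False),
    )
    # fail fast on a malformed precedence list when a catalog is resolvable
    cfg.load_tie_policy(cfg.load_catalog())
    return cfg
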