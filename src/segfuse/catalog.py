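"""Class catalogs for multi-class segmentation label spaces.

A :class:`ClassCatalog` is the ordered roster of pixel classes a study uses.
The default catalog covers the eight ovarian-ultrasound annotation classes —
chocolate cyst (CC), serous cystadenoma (SC), teratoma (T), theca cell tumor
(TCT), simple cyst (SCH), normal ovary (NO), mucinous cystadenoma (MC) and
high-grade serous cystadenoma (HGSC) — plus the ultrasound background (B).
Class ids are contiguous from 0 and double as pixel values in stored masks;
RGB colors are display-only metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence


@dataclass(frozen=True)
class ClassEntry:
    """One class in a catalog: integer id, short name, display color."""

    class_id: int
    name: str
    color: tuple[int, int, int]


@dataclass(frozen=True)
class ClassCatalog:
    """Ordered, contiguous class roster with a designated background class.

    Invariants (enforced at construction): ids are exactly 0..K-1 in entry
    order, names are distinct, and ``background_id`` names one entry.
    """

    entries: tuple[ClassEntry, ...]
    background_id: int

    def __post_init__(self) -> None:
        ids = [e.class_id for e in self.entries]
        if ids != list(range(len(self.entries))):
            raise ValueError(
                f"class ids must be contiguous from 0 in entry order, got {ids}"
            )
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate class names in catalog: {names}")
        if self.background_id not in ids:
            raise ValueError(
                f"background_id {self.background_id} is not a catalog class id"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ClassEntry]:
        return iter(self.entries)

    @property
    def class_ids(self) -> tuple[int, ...]:
        return tuple(e.class_id for e in self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    @property
    def tumor_ids(self) -> tuple[int, ...]:
        """Non-background class ids, in catalog order."""
        return tuple(e.class_id for e in self.entries if e.class_id != self.background_id)

    def id_of(self, name: str) -> int:
        for e in self.entries:
            if e.name == name:
                return e.class_id
        raise KeyError(f"unknown class name: {name!r}")

    def name_of(self, class_id: int) -> str:
        try:
            return self.entries[class_id].name
        except IndexError:
            raise KeyError(f"unknown class id: {class_id}") from None

    def to_json(self, path: str | Path) -> Path:
        """Write the catalog as a self-describing JSON file."""
        path = Path(path)
        payload = {
            "entries": [
                {"id": e.class_id, "name": e.name, "color": list(e.color)}
                for e in self.entries
            ],
            "background_id": self.background_id,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassCatalog":
        payload = json.loads(Path(path).read_text())
        entries = tuple(
            ClassEntry(e["id"], e["name"], tuple(e["color"]))
            for e in payload["entries"]
        )
        return cls(entries=entries, background_id=payload["background_id"])

    @classmethod
    def from_names(
        cls,
        names: Sequence[str],
        background: str,
        colors: Sequence[tuple[int, int, int]] | None = None,
    ) -> "ClassCatalog":
        """Build a catalog from an ordered name list; ids follow list order."""
        if colors is None:
            colors = [_DEFAULT_COLORS[i % len(_DEFAULT_COLORS)] for i in range(len(names))]
        entries = tuple(
            ClassEntry(i, n, tuple(c)) for i, (n, c) in enumerate(zip(names, colors))
        )
        return cls(entries=entries, background_id=list(names).index(background))


# Display palette: distinct hues for lesion classes, near-black for background.
_DEFAULT_COLORS: list[tuple[int, int, int]] = [
    (230, 25, 75),
    (60, 180, 75),
    (255, 225, 25),
    (0, 130, 200),
    (245, 130, 48),
    (145, 30, 180),
    (70, 240, 240),
    (240, 50, 230),
    (20, 20, 20),
]

#: Ovarian-ultrasound label space: 8 tumor/ovary classes + background, ids 0..8.
DEFAULT_CLASS_NAMES = ("CC", "SC", "T", "TCT", "SCH", "NO", "MC", "HGSC", "B")


def default_catalog() -> ClassCatalog:
    """The 9-class ovarian-ultrasound catalog (background last, id 8)."""
    return ClassCatalog.from_names(DEFAULT_CLASS_NAMES, background="B")
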