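"""Dataset manifest: labeled insect images with optional expert bounding boxes.

A manifest is the single exchange format of the package: a CSV with header
``record_id,image_path,family,species,genus,bbox,split`` where ``bbox`` holds
four comma-separated integers ``x_min,y_min,x_max,y_max`` (0-based, half-open)
and ``split`` is one of ``train``/``validation``/``test``/``unassigned``.
Manifests are inspectable without pixels: a missing image file only fails when
the pixels are actually loaded.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .families import DEFAULT_FAMILIES

SPLITS = ("train", "validation", "test", "unassigned")

MANIFEST_COLUMNS = ("record_id", "image_path", "family", "species", "genus", "bbox", "split")


class ManifestError(ValueError):
    """Raised when a manifest file or record violates an invariant."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in 0-based, half-open pixel coordinates.

    The box covers ``[x_min, x_max) x [y_min, y_max)``, so its width is
    ``x_max - x_min`` and height ``y_max - y_min``; both must be positive.
    """

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        for v in (self.x_min, self.y_min, self.x_max, self.y_max):
            if int(v) != v:
                raise ManifestError(f"bbox coordinates must be integers, got {v!r}")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ManifestError(
                f"bbox must have positive area: "
                f"({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    def to_string(self) -> str:
        return f"{self.x_min},{self.y_min},{self.x_max},{self.y_max}"

    @classmethod
    def from_string(cls, s: str) -> "BoundingBox":
        parts = s.split(",")
        if len(parts) != 4:
            raise ManifestError(f"malformed bbox string {s!r}: expected 4 comma-separated integers")
        try:
            coords = [int(p) for p in parts]
        except ValueError as exc:
            raise ManifestError(f"malformed bbox string {s!r}: non-integer field") from exc
        return cls(*coords)


@dataclass(frozen=True)
class ImageRecord:
    """One labeled image.

    ``species`` and ``genus`` are metadata only and never reach any
    prediction path: the classifier contract receives pixels exclusively.
    ``image_source`` is either a path (str) or an in-memory 8-bit RGB array.
    """

    record_id: str
    image_source: str | np.ndarray
    family: str
    species: str | None = None
    genus: str | None = None
    bbox: BoundingBox | None = None
    split: str = "unassigned"

    def __post_init__(self) -> None:
        if self.split not in SPLITS:
            raise ManifestError(f"record {self.record_id!r}: unknown split {self.split!r}")

    def load_image(self, root: str | Path | None = None) -> np.ndarray:
        """Return the 8-bit RGB pixel array (H, W, 3) for this record."""
        if isinstance(self.image_source, np.ndarray):
            return self.image_source
        path = Path(self.image_source)
        if root is not None and not path.is_absolute():
            path = Path(root) / path
        if not path.exists():
            raise FileNotFoundError(f"record {self.record_id!r}: image file not found: {path}")
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"), dtype=np.uint8)


@dataclass
class DatasetManifest:
    """Ordered collection of records plus an ordered label vocabulary."""

    records: list[ImageRecord] = field(default_factory=list)
    vocabulary: tuple[str, ...] = DEFAULT_FAMILIES
    root: str | None = None  # base directory for relative image paths

    def __post_init__(self) -> None:
        self.vocabulary = tuple(self.vocabulary)
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ManifestError("vocabulary contains duplicate labels")
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise ManifestError(f"duplicate record_id {rec.record_id!r}")
            seen.add(rec.record_id)
            if rec.family not in self.vocabulary:
                raise ManifestError(
                    f"record {rec.record_id!r}: family {rec.family!r} not in vocabulary"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ImageRecord]:
        return iter(self.records)

    def family_counts(self) -> dict[str, int]:
        counts = Counter(r.family for r in self.records)
        return {f: counts.get(f, 0) for f in self.vocabulary if counts.get(f, 0) or f in counts}

    def subset(self, split: str) -> "DatasetManifest":
        if split not in SPLITS:
            raise ManifestError(f"unknown split {split!r}")
        return DatasetManifest(
            records=[r for r in self.records if r.split == split],
            vocabulary=self.vocabulary,
            root=self.root,
        )

    def with_records(self, records: Sequence[ImageRecord]) -> "DatasetManifest":
        return DatasetManifest(records=list(records), vocabulary=self.vocabulary, root=self.root)


def read_manifest(path: str | Path, vocabulary: Sequence[str] | None = None) -> DatasetManifest:
    """Parse a manifest CSV.

    Required columns: ``record_id``, ``image_path``, ``family``. Optional:
    ``species``, ``genus``, ``bbox``, ``split``. Malformed bbox strings are
    rejected with an error naming the offending record, never silently dropped.
    When ``vocabulary`` is None the vocabulary is inferred from the distinct
    families in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("record_id", "image_path", "family"):
        if col not in df.columns:
            raise ManifestError(f"manifest {path} missing required column {col!r}")

    dup = df["record_id"][df["record_id"].duplicated()]
    if len(dup):
        raise ManifestError(f"duplicate record_id {dup.iloc[0]!r} in {path}")

    if vocabulary is None:
        vocabulary = tuple(dict.fromkeys(df["family"]))

    records: list[ImageRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        bbox_s = d.get("bbox", "")
        try:
            bbox = BoundingBox.from_string(bbox_s) if bbox_s else None
        except ManifestError as exc:
            raise ManifestError(f"record {d['record_id']!r}: {exc}") from exc
        records.append(
            ImageRecord(
                record_id=d["record_id"],
                image_source=d["image_path"],
                family=d["family"],
                species=d.get("species") or None,
                genus=d.get("genus") or None,
                bbox=bbox,
                split=d.get("split") or "unassigned",
            )
        )
    return DatasetManifest(records=records, vocabulary=vocabulary, root=str(path.parent))


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write a manifest CSV with deterministic column order and rows sorted by record_id."""
    rows = []
    for r in sorted(manifest.records, key=lambda r: r.record_id):
        if isinstance(r.image_source, np.ndarray):
            raise ManifestError(
                f"record {r.record_id!r}: in-memory images cannot be serialized to a manifest"
            )
        rows.append(
            {
                "record_id": r.record_id,
                "image_path": r.image_source,
                "family": r.family,
                "species": r.species or "",
                "genus": r.genus or "",
                "bbox": r.bbox.to_string() if r.bbox else "",
                "split": r.split,
            }
        )
    df = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    df.to_csv(path, index=False)


def crop_to_bbox(image: np.ndarray, bbox: BoundingBox) -> np.ndarray:
    """Crop an (H, W, 3) array to a bounding box; pixels are copied unchanged."""
    h, w = image.shape[:2]
    if bbox.x_min < 0 or bbox.y_min < 0 or bbox.x_max > w or bbox.y_max > h:
        raise ManifestError(
            f"bbox ({bbox.to_string()}) exceeds image bounds {w}x{h}"
        )
    return image[bbox.y_min : bbox.y_max, bbox.x_min : bbox.x_max].copy()


def summarize_counts(manifest: DatasetManifest) -> dict[str, tuple[int, int, int]]:
    """Per-family (n_images, n_species, n_genera); metadata counts skip empty values."""
    out: dict[str, tuple[int, int, int]] = {}
    by_family: dict[str, list[ImageRecord]] = {}
    for r in manifest.records:
        by_family.setdefault(r.family, []).append(r)
    for family, recs in by_family.items():
        species = {r.species for r in recs if r.species}
        genera = {r.genus for r in recs if r.genus}
        out[family] = (len(recs), len(species), len(genera))
    return out
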