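"""Stratified 60/20/20 partition of a manifest into train/validation/test.

Each family contributes its images independently: ``floor(0.6 n)`` to
training, then the remainder is halved with the odd image (if any) going to
the test set. This floor/floor/remainder rule reproduces the published
per-family split counts exactly, including every odd-remainder family.
Membership within a family is decided by a seeded shuffle; counts are a pure
function of the family totals and never depend on the seed or row order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .manifest import DatasetManifest, ImageRecord, ManifestError


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.6
    val_fraction: float = 0.2
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_fraction, self.val_fraction, self.test_fraction)
        if any(f < 0 for f in fracs):
            raise ValueError("split fractions must be nonnegative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(fracs)}")


@dataclass
class SplitAssignment:
    """Per-family (n_train, n_val, n_test) counts of a completed split."""

    per_family: dict[str, tuple[int, int, int]]

    def totals(self) -> tuple[int, int, int]:
        cols = list(zip(*self.per_family.values())) or [[], [], []]
        return tuple(sum(c) for c in cols)  # type: ignore[return-value]


def allocate_counts(family_total: int, spec: SplitSpec = SplitSpec()) -> tuple[int, int, int]:
    """Split one family's image count into (n_train, n_val, n_test).

    n_train = floor(train_fraction * total); the remainder is split between
    validation and test with validation taking the floor of its proportional
    share, so under the default 20/20 fractions an odd remainder's extra
    image lands in the test set.
    """
    if family_total < 0:
        raise ValueError(f"family total must be nonnegative, got {family_total}")
    n_train = math.floor(spec.train_fraction * family_total)
    remainder = family_total - n_train
    rest = spec.val_fraction + spec.test_fraction
    share = spec.val_fraction / rest if rest > 0 else 0.0
    n_val = math.floor(remainder * share)
    n_test = remainder - n_val
    return n_train, n_val, n_test


def stratified_split(
    manifest: DatasetManifest,
    spec: SplitSpec = SplitSpec(),
    force: bool = False,
) -> tuple[DatasetManifest, SplitAssignment]:
    """Assign every record a split tag, stratified by family.

    Within each family the records are shuffled with a seed derived from
    ``spec.seed`` and the family name, then assigned contiguously to
    train/validation/test with :func:`allocate_counts` sizes. Deterministic
    given (manifest order, seed); shuffling the manifest rows changes
    membership but never the per-family counts.
    """
    if not manifest.vocabulary:
        raise ManifestError("cannot split a manifest with an empty vocabulary")
    if not force:
        assigned = [r.record_id for r in manifest.records if r.split != "unassigned"]
        if assigned:
            raise ManifestError(
                f"record {assigned[0]!r} already has a split tag; pass force=True to reassign"
            )

    by_family: dict[str, list[int]] = {f: [] for f in manifest.vocabulary}
    for i, rec in enumerate(manifest.records):
        by_family[rec.family].append(i)

    new_records: list[ImageRecord] = list(manifest.records)
    per_family: dict[str, tuple[int, int, int]] = {}
    for family in manifest.vocabulary:
        idx = np.array(by_family[family], dtype=np.int64)
        n_train, n_val, n_test = allocate_counts(len(idx), spec)
        per_family[family] = (n_train, n_val, n_test)
        # per-family stream keeps the shuffle independent of other families
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed % (2**31), _stable_hash(family)])
        )
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            if j < n_train:
                tag = "train"
            elif j < n_train + n_val:
                tag = "validation"
            else:
                tag = "test"
            new_records[i] = replace(new_records[i], split=tag)

    return manifest.with_records(new_records), SplitAssignment(per_family)


def _stable_hash(s: str) -> int:
    """Process-independent 32-bit hash (Python's hash() is salted)."""
    import zlib

    return zlib.crc32(s.encode("utf-8"))
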