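"""Procedural generator of labeled virtual-insect images with tight boxes.

Every other module gets a download-free, seed-deterministic test surface
from here. Each family is a prototype parameter bundle (body hue and
aspect, wing size and angle, bristle density, leg rendering); individual
specimens jitter around their family prototype, are scaled so the specimen
covers a controlled fraction of the image area, and are composited onto
either a uniform or a cluttered background. The renderer tracks the exact
specimen mask, so the stored bounding box is tight by construction.

``family_similarity`` in [0, 1] linearly shrinks all prototypes toward
their common mean: at 0 the families are well separated in parameter space
(hues alone are spaced 1/K apart), at 1 they coincide and only the
within-family jitter remains. This makes class confusion a controlled,
monotone quantity rather than an accident of the renderer.

The generator emulates the statistical structure the study design cares
about — class imbalance, small specimen-to-image area fractions, background
clutter, expert-tight boxes — not insect photorealism.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import draw as skdraw

from .manifest import BoundingBox, DatasetManifest, ImageRecord, crop_to_bbox
from .splitting import SplitSpec, stratified_split

# prototype vector layout
_PARAM_NAMES = (
    "hue",
    "body_aspect",
    "wing_size",
    "wing_angle",
    "bristle_density",
    "legs",
    "saturation",
    "value",
)


@dataclass(frozen=True)
class SyntheticSpec:
    n_families: int = 6
    images_per_family: int | dict[str, int] = 50
    image_size: int = 128
    specimen_area_fraction_range: tuple[float, float] = (0.02, 0.3)
    background: str = "cluttered"  # or "uniform"
    clutter_density: float = 0.5
    family_similarity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 2:
            raise ValueError("need at least 2 families")
        lo, hi = self.specimen_area_fraction_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("specimen area fractions must lie in (0, 1]")
        if self.background not in ("uniform", "cluttered"):
            raise ValueError(f"unknown background {self.background!r}")
        if not 0.0 <= self.family_similarity <= 1.0:
            raise ValueError("family_similarity must be in [0, 1]")
        counts = self.counts()
        if any(c < 0 for c in counts.values()):
            raise ValueError("image counts must be nonnegative")

    def family_names(self) -> tuple[str, ...]:
        return tuple(f"family_{i:02d}" for i in range(self.n_families))

    def counts(self) -> dict[str, int]:
        names = self.family_names()
        if isinstance(self.images_per_family, dict):
            return {n: int(self.images_per_family.get(n, 0)) for n in names}
        return {n: int(self.images_per_family) for n in names}


def imbalanced_counts(n_families: int, base: int = 200, rare_factor: float = 0.25) -> dict[str, int]:
    """Mildly imbalanced per-family counts: the last family ~4x rarer.

    Mirrors the kind of imbalance real corpora show, where one family (the
    rare-family analogue) has far fewer images than the rest.
    """
    names = tuple(f"family_{i:02d}" for i in range(n_families))
    counts = {n: base for n in names}
    counts[names[-1]] = max(1, int(round(base * rare_factor)))
    return counts


def family_prototypes(spec: SyntheticSpec) -> np.ndarray:
    """(K, 8) prototype matrix, deterministic in the spec seed.

    Hues are spaced evenly around the color wheel so at family_similarity 0
    any two prototypes differ by at least 1/K in hue alone; the similarity
    parameter interpolates every prototype toward the common mean.
    """
    k = spec.n_families
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed % (2**31), 0xB0D7]))
    protos = np.zeros((k, len(_PARAM_NAMES)))
    protos[:, 0] = (np.arange(k) / k + rng.uniform(0, 1 / (4 * k), k)) % 1.0  # hue
    protos[:, 1] = np.linspace(0.35, 0.75, k)[rng.permutation(k)]  # body aspect
    protos[:, 2] = np.linspace(0.5, 1.1, k)[rng.permutation(k)]  # wing size
    protos[:, 3] = np.linspace(0.3, 1.1, k)[rng.permutation(k)]  # wing angle (rad)
    protos[:, 4] = np.linspace(0.0, 1.0, k)[rng.permutation(k)]  # bristle density
    protos[:, 5] = (np.arange(k) % 2).astype(float)  # legs on/off
    protos[:, 6] = rng.uniform(0.6, 0.9, k)  # saturation
    protos[:, 7] = rng.uniform(0.5, 0.9, k)  # value
    s = spec.family_similarity
    mean = protos.mean(axis=0, keepdims=True)
    return (1 - s) * protos + s * mean


def _background(size: int, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    base = rng.uniform(0.25, 0.75, size=3)
    img = np.ones((size, size, 3)) * base
    if spec.background == "uniform":
        return img
    n_blobs = int(spec.clutter_density * 40) + 5
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, size, 2)
        ry, rx = rng.uniform(size * 0.03, size * 0.18, 2)
        color = rng.uniform(0, 1, size=3)
        rr, cc = skdraw.ellipse(cy, cx, ry, rx, shape=(size, size), rotation=rng.uniform(0, np.pi))
        img[rr, cc] = 0.5 * img[rr, cc] + 0.5 * color
    img += rng.normal(0, 0.03, img.shape)
    return np.clip(img, 0, 1)


def render_image(
    spec: SyntheticSpec, prototype: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one specimen. Returns (uint8 RGB image, boolean mask, param vector).

    The specimen is a body ellipse with two wing ellipses, optional legs
    and bristle speckles, placed at a random position and scaled so the
    final specimen mask covers an area fraction drawn from the spec range.
    """
    size = spec.image_size
    params = prototype.copy()
    jitter = np.array([0.02, 0.03, 0.05, 0.05, 0.05, 0.0, 0.03, 0.03])
    params += rng.normal(0, 1, len(params)) * jitter
    params[0] %= 1.0
    params[1:] = np.clip(params[1:], 0.05, 1.2)

    hue, aspect, wing_size, wing_angle, bristle, legs, sat, val = params
    area_frac = rng.uniform(*spec.specimen_area_fraction_range)
    # body covers ~55% of the specimen mask; solve the body half-width from that
    body_area = 0.55 * area_frac * size * size
    rx = np.sqrt(body_area / (np.pi * aspect))
    ry = aspect * rx
    extent = rx * (1 + wing_size)  # wings stick out along the body axis
    margin = min(size / 2 - 1, extent)
    cy = rng.uniform(margin, size - margin) if size - margin > margin else size / 2
    cx = rng.uniform(margin, size - margin) if size - margin > margin else size / 2
    rot = rng.uniform(0, np.pi)

    mask = np.zeros((size, size), dtype=bool)
    body_rr, body_cc = skdraw.ellipse(cy, cx, ry, rx, shape=(size, size), rotation=rot)
    mask[body_rr, body_cc] = True

    wing_rr_cc = []
    for sign in (-1, 1):
        wr = max(1.0, ry * wing_size * 1.6)
        wc = max(1.0, rx * wing_size * 0.5)
        ang = rot + sign * wing_angle
        wy = cy + sign * np.sin(ang) * (ry + wr * 0.6)
        wx = cx + sign * np.cos(ang) * (ry + wr * 0.6)
        rr, cc = skdraw.ellipse(wy, wx, wr, wc, shape=(size, size), rotation=ang)
        wing_rr_cc.append((rr, cc))
        mask[rr, cc] = True

    leg_px: list[tuple[np.ndarray, np.ndarray]] = []
    if legs > 0.5:
        for i in range(6):
            ang = rot + np.pi / 2 + (i - 2.5) * 0.35
            y0, x0 = cy + np.sin(ang) * ry * 0.6, cx + np.cos(ang) * rx * 0.6
            y1 = y0 + np.sin(ang) * ry * 1.6
            x1 = x0 + np.cos(ang) * rx * 1.6
            rr, cc = skdraw.line(
                int(np.clip(y0, 0, size - 1)),
                int(np.clip(x0, 0, size - 1)),
                int(np.clip(y1, 0, size - 1)),
                int(np.clip(x1, 0, size - 1)),
            )
            leg_px.append((rr, cc))
            mask[rr, cc] = True

    n_bristles = int(bristle * 30)
    br_pts = []
    if n_bristles and len(body_rr):
        pick = rng.integers(0, len(body_rr), n_bristles)
        off = rng.integers(-2, 3, size=(n_bristles, 2))
        by = np.clip(body_rr[pick] + off[:, 0], 0, size - 1)
        bx = np.clip(body_cc[pick] + off[:, 1], 0, size - 1)
        br_pts = [(by, bx)]
        mask[by, bx] = True

    img = _background(size, spec, rng)
    body_color = np.array(colorsys.hsv_to_rgb(hue, sat, val))
    wing_color = np.clip(body_color * 0.5 + 0.45, 0, 1)
    for rr, cc in wing_rr_cc:
        img[rr, cc] = 0.45 * img[rr, cc] + 0.55 * wing_color
    img[body_rr, body_cc] = body_color
    dark = np.clip(body_color * 0.4, 0, 1)
    for rr, cc in leg_px:
        img[rr, cc] = dark
    for by, bx in br_pts:
        img[by, bx] = dark

    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8), mask, params


def tight_bbox(mask: np.ndarray) -> BoundingBox:
    ys, xs = np.nonzero(mask)
    return BoundingBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)


@dataclass
class GenerationResult:
    manifest: DatasetManifest
    prototypes: np.ndarray  # (K, 8)
    record_params: dict[str, np.ndarray] = field(default_factory=dict)
    masks: dict[str, np.ndarray] = field(default_factory=dict)


def generate_dataset(
    spec: SyntheticSpec,
    out_dir: str | Path | None = None,
    keep_masks: bool = False,
) -> GenerationResult:
    """Generate the full dataset; byte-identical regeneration from one seed.

    With ``out_dir`` the images are written as PNGs and the manifest
    references them by relative path; without it the records hold in-memory
    arrays (faster for tests). ``record_params`` carries each specimen's
    rendered parameter vector so label recoverability can be checked against
    the prototypes.
    """
    protos = family_prototypes(spec)
    names = spec.family_names()
    counts = spec.counts()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    records: list[ImageRecord] = []
    result = GenerationResult(manifest=None, prototypes=protos)  # type: ignore[arg-type]
    for fi, family in enumerate(names):
        for j in range(counts[family]):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed % (2**31), fi, j])
            )
            img, mask, params = render_image(spec, protos[fi], rng)
            rid = f"{family}_{j:04d}"
            bbox = tight_bbox(mask)
            if out_dir is not None:
                fname = f"{rid}.png"
                Image.fromarray(img).save(out_dir / fname)
                source: str | np.ndarray = fname
            else:
                source = img
            records.append(ImageRecord(record_id=rid, image_source=source, family=family, bbox=bbox))
            result.record_params[rid] = params
            if keep_masks:
                result.masks[rid] = mask

    result.manifest = DatasetManifest(
        records=records,
        vocabulary=names,
        root=str(out_dir) if out_dir is not None else None,
    )
    return result


def crop_effect_fixture(
    spec: SyntheticSpec, split_seed: int = 0
) -> tuple[DatasetManifest, DatasetManifest]:
    """Paired (uncropped, cropped) in-memory manifests with identical ids and splits.

    The cropped twin applies each record's tight bounding box to its pixels;
    everything else — record ids, labels, split tags — is shared, so any
    performance difference between the pair is attributable to the crop.
    """
    result = generate_dataset(spec, out_dir=None)
    manifest, _ = stratified_split(result.manifest, SplitSpec(seed=split_seed))
    cropped_records = []
    for rec in manifest.records:
        if rec.bbox is None:
            raise ValueError(f"record {rec.record_id!r} lacks a bounding box")
        img = rec.load_image()
        cropped_records.append(
            ImageRecord(
                record_id=rec.record_id,
                image_source=crop_to_bbox(img, rec.bbox),
                family=rec.family,
                bbox=None,
                split=rec.split,
            )
        )
    cropped = DatasetManifest(records=cropped_records, vocabulary=manifest.vocabulary)
    return manifest, cropped
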