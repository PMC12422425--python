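"""Deterministic preprocessing and the stochastic test-time augmentation policy.

Preprocessing is resize-to-target followed by per-channel z-score
normalization with ImageNet statistics (means 0.485/0.456/0.406, stds
0.229/0.224/0.225). The augmentation policy is an ordered list of
(group, technique, p) entries applied independently: on every pass each
technique fires with its own probability, so repeated passes over one image
sample the aleatoric variability of the input. The same policy is used
during training and at test time.

All augmentations operate on float arrays in [0, 1] of shape (H, W, 3) and
preserve shape and channel count. Given an identical random generator state
the output is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform
from skimage.filters import gaussian as _gaussian_blur

IMAGENET_MEANS = (0.485, 0.456, 0.406)
IMAGENET_STDS = (0.229, 0.224, 0.225)


class PolicyError(ValueError):
    """Raised for invalid augmentation policies or missing donor images."""


@dataclass(frozen=True)
class PreprocessSpec:
    target_size: tuple[int, int] = (640, 640)  # (height, width)
    channel_means: tuple[float, float, float] = IMAGENET_MEANS
    channel_stds: tuple[float, float, float] = IMAGENET_STDS

    def __post_init__(self) -> None:
        if self.target_size[0] <= 0 or self.target_size[1] <= 0:
            raise ValueError("target dimensions must be positive")
        if any(s <= 0 for s in self.channel_stds):
            raise ValueError("channel stds must be strictly positive")


def resize(image: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """Resize to the target size, ignoring aspect ratio (anisotropic, no padding).

    Bilinear interpolation with anti-aliasing on downscale; returns a float
    array in [0, 1] regardless of input dtype.
    """
    if image.size == 0:
        raise ValueError("cannot resize an empty image")
    img = _as_float01(image)
    h, w = spec.target_size
    if img.shape[:2] == (h, w):
        return img
    return sktransform.resize(img, (h, w), order=1, anti_aliasing=True, preserve_range=True)


def zscore_normalize(image: np.ndarray, spec: PreprocessSpec = PreprocessSpec()) -> np.ndarray:
    """Per-channel z-score: (pixel/255 - mean_c) / std_c for 8-bit input.

    Float input is assumed already scaled to [0, 1].
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    img = _as_float01(image)
    means = np.asarray(spec.channel_means, dtype=np.float64)
    stds = np.asarray(spec.channel_stds, dtype=np.float64)
    return (img - means) / stds


def preprocess(image: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """resize then z-score normalize; the deterministic half of the pipeline."""
    return zscore_normalize(resize(image, spec), spec)


def _as_float01(image: np.ndarray) -> np.ndarray:
    if image.dtype == np.uint8:
        return image.astype(np.float64) / 255.0
    return image.astype(np.float64, copy=False)


# ---------------------------------------------------------------------------
# Augmentation techniques
# ---------------------------------------------------------------------------


def _horizontal_flip(img: np.ndarray, rng: np.random.Generator, params: dict) -> np.ndarray:
    # p=1.0 entry: the op is always invoked; with randomized=True (default)
    # the flip itself happens with internal probability 0.5 so the pass
    # ensemble keeps its stochasticity.
    if params.get("randomized", True) and rng.random() >= 0.5:
        return img
    return img[:, ::-1].copy()


def _rotation90(img: np.ndarray, rng: np.random.Generator, params: dict) -> np.ndarray:
    k = int(rng.integers(0, 4)) if params.get("randomized", True) else 1
    return np.rot90(img, k=k).copy() if k else img


def _color_jitter(img: np.ndarray, rng: np.random.Generator, params: dict) -> np.ndarray:
    strength = params.get("strength", 0.1)
    brightness = 1.0 + rng.uniform(-strength, strength)
    contrast = 1.0 + rng.uniform(-strength, strength)
    saturation = 1.0 + rng.uniform(-strength, strength)
    out = img * brightness
    mean = out.mean()
    out = (out - mean) * contrast + mean
    gray = out.mean(axis=2, keepdims=True)
    out = gray + (out - gray) * saturation
    return np.clip(out, 0.0, 1.0)


def _channel_shuffle(img: np.ndarray, rng: np.random.Generator, params: dict) -> np.ndarray:
    return img[:, :, rng.permutation(3)]


def _gaussian_noise(img: np.ndarray, rng: np.random.Generator, params: dict) -> np.ndarray:
    lo, hi = params.get("sigma_range", (0.01, 0.05))
    sigma = rng.uniform(lo, hi)
    return np.clip(img + rng.normal(0.0, sigma, size=img.shape), 0.0, 1.0)


def _median_blur(img: np.ndarray, rng: np.random.Generator, params: dict) -> np.ndarray:
    size = params.get("size", 3)
    return ndimage.median_filter(img, size=(size, size, 1))


def _sharpness(img: np.ndarray, rng: np.random.Generator, params: dict) -> np.ndarray:
    lo, hi = params.get("amount_range", (0.5, 1.5))
    amount = rng.uniform(lo, hi)
    blurred = _gaussian_blur(img, sigma=1.0, channel_axis=2)
    return np.clip(img + amount * (img - blurred), 0.0, 1.0)


def _thin_plate_spline(img: np.ndarray, rng: np.random.Generator, params: dict) -> np.ndarray:
    # mild warp: 4x4 control grid, displacements <= 5% of the image size
    grid = params.get("grid", 4)
    max_disp = params.get("max_displacement", 0.05)
    h, w = img.shape[:2]
    ys = np.linspace(0, h - 1, grid)
    xs = np.linspace(0, w - 1, grid)
    src = np.array([(x, y) for y in ys for x in xs], dtype=np.float64)
    disp = rng.uniform(-max_disp, max_disp, size=src.shape) * np.array([w, h])
    tps = sktransform.ThinPlateSplineTransform.from_estimate(src, src + disp)
    out = sktransform.warp(img, tps, mode="reflect", preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def _crop_quadrant(img: np.ndarray, rng: np.random.Generator, params: dict) -> np.ndarray:
    # "Crop (2x2)": pick one of the four half-size quadrants, resize back up
    h, w = img.shape[:2]
    q = int(rng.integers(0, 4))
    y0 = (q // 2) * (h // 2)
    x0 = (q % 2) * (w // 2)
    crop = img[y0 : y0 + h // 2, x0 : x0 + w // 2]
    return sktransform.resize(crop, (h, w), order=1, anti_aliasing=False, preserve_range=True)


def _random_erasing(img: np.ndarray, rng: np.random.Generator, params: dict) -> np.ndarray:
    lo, hi = params.get("area_range", (0.02, 0.1))
    h, w = img.shape[:2]
    area = rng.uniform(lo, hi) * h * w
    aspect = rng.uniform(0.5, 2.0)
    eh = max(1, min(h, int(round(np.sqrt(area * aspect)))))
    ew = max(1, min(w, int(round(np.sqrt(area / aspect)))))
    y0 = int(rng.integers(0, h - eh + 1))
    x0 = int(rng.integers(0, w - ew + 1))
    out = img.copy()
    out[y0 : y0 + eh, x0 : x0 + ew] = rng.uniform(0.0, 1.0, size=(eh, ew, img.shape[2]))
    return out


def _cutmix(
    img: np.ndarray, rng: np.random.Generator, params: dict, donor: np.ndarray
) -> np.ndarray:
    lo, hi = params.get("area_range", (0.1, 0.4))
    h, w = img.shape[:2]
    frac = rng.uniform(lo, hi)
    ph = max(1, int(round(h * np.sqrt(frac))))
    pw = max(1, int(round(w * np.sqrt(frac))))
    y0 = int(rng.integers(0, h - ph + 1))
    x0 = int(rng.integers(0, w - pw + 1))
    out = img.copy()
    out[y0 : y0 + ph, x0 : x0 + pw] = donor[y0 : y0 + ph, x0 : x0 + pw]
    return out


_TECHNIQUES: dict[str, Callable] = {
    "horizontal_flip": _horizontal_flip,
    "rotation_90": _rotation90,
    "color_jitter": _color_jitter,
    "channel_shuffle": _channel_shuffle,
    "gaussian_noise": _gaussian_noise,
    "median_blur": _median_blur,
    "sharpness": _sharpness,
    "thin_plate_spline": _thin_plate_spline,
    "crop_2x2": _crop_quadrant,
    "random_erasing": _random_erasing,
    "cutmix_v2": _cutmix,
}


@dataclass(frozen=True)
class AugmentationStep:
    group: str
    technique: str
    p: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise PolicyError(f"{self.technique}: probability {self.p} outside [0, 1]")
        if self.technique not in _TECHNIQUES:
            raise PolicyError(f"unknown augmentation technique {self.technique!r}")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Ordered schedule of stochastic augmentations.

    ``apply_mix_at_test`` controls whether the Mix group (CutMix) also runs
    at test time; when it does, a donor image from the same evaluation set
    must be supplied to :func:`apply_policy`.
    """

    steps: tuple[AugmentationStep, ...]
    apply_mix_at_test: bool = True

    def firing_probabilities(self) -> dict[str, float]:
        return {s.technique: s.p for s in self.steps}

    def to_config(self) -> dict:
        return {
            "apply_mix_at_test": self.apply_mix_at_test,
            "steps": [
                {"group": s.group, "technique": s.technique, "p": s.p, **({"params": dict(s.params)} if s.params else {})}
                for s in self.steps
            ],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "AugmentationPolicy":
        steps = tuple(
            AugmentationStep(d["group"], d["technique"], float(d["p"]), d.get("params", {}))
            for d in cfg["steps"]
        )
        return cls(steps=steps, apply_mix_at_test=bool(cfg.get("apply_mix_at_test", True)))


def default_policy(
    apply_mix_at_test: bool = True, basic_randomized: bool = True
) -> AugmentationPolicy:
    """The canonical 11-technique schedule.

    Basic group (flip, 90-degree rotation) at p=1.0: the op is invoked on
    every pass with its internal parameter random (flip coin, rotation angle
    from {0, 90, 180, 270} degrees) unless ``basic_randomized`` is False, in
    which case the fixed transform is applied on every pass. Color, Geometric
    and Mix techniques each fire independently at p=0.1.
    """
    b = {"randomized": basic_randomized}
    steps = (
        AugmentationStep("Basic", "horizontal_flip", 1.0, b),
        AugmentationStep("Basic", "rotation_90", 1.0, b),
        AugmentationStep("Color", "color_jitter", 0.1),
        AugmentationStep("Color", "channel_shuffle", 0.1),
        AugmentationStep("Color", "gaussian_noise", 0.1),
        AugmentationStep("Color", "median_blur", 0.1),
        AugmentationStep("Color", "sharpness", 0.1),
        AugmentationStep("Geom.", "thin_plate_spline", 0.1),
        AugmentationStep("Geom.", "crop_2x2", 0.1),
        AugmentationStep("Geom.", "random_erasing", 0.1),
        AugmentationStep("Mix", "cutmix_v2", 0.1),
    )
    return AugmentationPolicy(steps=steps, apply_mix_at_test=apply_mix_at_test)


def save_policy(policy: AugmentationPolicy, path) -> None:
    """Write a policy as a YAML config block mirroring the Group/Technique/p table."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(policy.to_config(), fh, sort_keys=False)


def load_policy(path) -> AugmentationPolicy:
    import yaml

    with open(path) as fh:
        return AugmentationPolicy.from_config(yaml.safe_load(fh))


def identity_policy() -> AugmentationPolicy:
    """A policy in which nothing ever fires; useful as a no-TTA control."""
    return AugmentationPolicy(steps=(), apply_mix_at_test=False)


def apply_policy(
    image: np.ndarray,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
    donor: np.ndarray | None = None,
    stage: str = "test",
    return_log: bool = False,
) -> np.ndarray | tuple[np.ndarray, list[str]]:
    """Run one stochastic pass of the policy over a [0, 1] float image.

    Each step fires independently with its probability ``p``; the output has
    the same shape as the input. ``donor`` supplies the CutMix counterpart
    image. With ``return_log`` the list of techniques that actually fired is
    returned alongside the image (the fire/no-fire decision for the Basic
    group counts the op invocation, not the internal coin).
    """
    img = _as_float01(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    fired: list[str] = []
    for step in policy.steps:
        if step.group == "Mix" and stage != "train" and not policy.apply_mix_at_test:
            continue
        if rng.random() >= step.p:
            continue
        fn = _TECHNIQUES[step.technique]
        if step.technique == "cutmix_v2":
            if donor is None:
                raise PolicyError(
                    "CutMix fired but no donor image is available; supply one or "
                    "set apply_mix_at_test=False"
                )
            img = fn(img, rng, step.params, _as_float01(donor))
        else:
            img = fn(img, rng, step.params)
        fired.append(step.technique)
    if return_log:
        return img, fired
    return img
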