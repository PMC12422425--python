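import numpy as np
import pytest

from flyconf import DatasetManifest, ImageRecord, PreprocessSpec
from flyconf.preprocess import IMAGENET_MEANS, IMAGENET_STDS


def encode_class_image(class_index: int, size: int = 16) -> np.ndarray:
    """Constant 8-bit image whose pixel value encodes a class index (step 10)."""
    return np.full((size, size, 3), 10 * class_index, dtype=np.uint8)


def decode_class(normalized_image: np.ndarray) -> int:
    """Invert the preprocessing on an encoded image to recover its class."""
    v = normalized_image[0, 0, 0] * IMAGENET_STDS[0] + IMAGENET_MEANS[0]
    return int(round(v * 255 / 10))


class DeterministicStub:
    """Classifier emitting one fixed probability vector for every input."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=np.float64)
        self.n_classes = len(self.probs)

    def predict_proba(self, image, rng=None, dropout=False):
        return self.probs.copy()


class BernoulliStub:
    """Emits the image's encoded true class with probability p, else a uniform
    draw over the other classes. Requires an rng (its only stochasticity)."""

    def __init__(self, n_classes: int, p: float):
        self.n_classes = n_classes
        self.p = p

    def predict_proba(self, image, rng=None, dropout=False):
        true = decode_class(image)
        if rng.random() < self.p:
            label = true
        else:
            others = [k for k in range(self.n_classes) if k != true]
            label = others[rng.integers(len(others))]
        out = np.full(self.n_classes, 1e-6)
        out[label] = 1.0
        return out / out.sum()


@pytest.fixture
def stub_spec():
    """Preprocess spec matching the encoded stub images (no resizing artifacts)."""
    return PreprocessSpec(target_size=(16, 16))


@pytest.fixture
def tiny_manifest():
    recs = [
        ImageRecord("r1", encode_class_image(0), "A", species="sp1", genus="g1"),
        ImageRecord("r2", encode_class_image(0), "A", species="sp2", genus="g1"),
        ImageRecord("r3", encode_class_image(1), "B", species="sp3", genus="g2"),
    ]
    return DatasetManifest(records=recs, vocabulary=("A", "B"))


@pytest.fixture
def separable_manifest():
    """Two-class, linearly separable color blobs with mild noise, split 60/20/20."""
    rng = np.random.default_rng(42)
    recs = []
    for cls, family in enumerate(["red_like", "blue_like"]):
        for i in range(50):
            img = np.zeros((16, 16, 3))
            img[..., 2 * cls] = 0.8  # channel 0 for class 0, channel 2 for class 1
            img += rng.normal(0, 0.05, img.shape)
            img = (np.clip(img, 0, 1) * 255).astype(np.uint8)
            split = "train" if i < 30 else ("validation" if i < 40 else "test")
            recs.append(
                ImageRecord(f"{family}_{i}", img, family, split=split)
            )
    return DatasetManifest(records=recs, vocabulary=("red_like", "blue_like"))
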