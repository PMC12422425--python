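"""Stochastic classifier contract, a small trainable CNN, and the training recipe.

Any object exposing ``n_classes`` and
``predict_proba(image, rng, dropout) -> probability vector`` satisfies the
contract that the Monte Carlo predictor consumes; the classifier only ever
sees pixels (taxonomic metadata never reaches a prediction path).

:class:`ReferenceNet` is a compact convolutional network (three 3x3 conv
blocks, global average pooling, a linear head; well under 200k parameters)
written directly on numpy so training runs anywhere. A dropout layer is
attached to every weighted layer — after each convolution's activation and
on the input of the linear head — and stays active at test time when
``dropout=True``, which is what turns repeated forward passes into Monte
Carlo samples of the model posterior.

The training recipe: label-smoothed cross-entropy, AdamW, base learning
rate modulated by cosine annealing with warm restarts, best checkpoint by
minimum validation loss, optional early stopping.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .manifest import DatasetManifest
from .preprocess import AugmentationPolicy, PreprocessSpec, apply_policy, resize, zscore_normalize


@runtime_checkable
class ClassifierContract(Protocol):
    n_classes: int

    def predict_proba(
        self, image: np.ndarray, rng: np.random.Generator | None = None, dropout: bool = False
    ) -> np.ndarray: ...


def smoothed_cross_entropy(probs: np.ndarray, true_index: int, smoothing: float = 0.1) -> float:
    """Cross-entropy against a label-smoothed target.

    With smoothing eps the target is q = (1-eps)*onehot + eps/K, so the loss
    is -sum_k q_k log p_k. Probabilities are clamped at 1e-12 so a zero
    probability at a smoothed class stays finite.
    """
    p = np.asarray(probs, dtype=np.float64)
    if not 0.0 <= smoothing < 1.0:
        raise ValueError(f"smoothing must be in [0, 1), got {smoothing}")
    k = p.shape[-1]
    if not 0 <= true_index < k:
        raise ValueError(f"true class index {true_index} outside [0, {k})")
    q = np.full(k, smoothing / k)
    q[true_index] += 1.0 - smoothing
    return float(-(q * np.log(np.clip(p, 1e-12, None))).sum())


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 100
    batch_size: int = 32
    label_smoothing: float = 0.1
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    restart_period: int = 10  # T0 of the warm-restart schedule, in epochs
    restart_mult: int = 2
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label_smoothing must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


def cosine_warm_restart_factor(epoch: int, period: int = 10, mult: int = 2) -> float:
    """Multiplier in [0, 1] for the base learning rate at a given epoch.

    The schedule restarts at full rate every ``period`` epochs, the period
    growing by ``mult`` after each restart, and decays to 0 along a cosine
    within each period.
    """
    t, t_i = epoch, period
    while t >= t_i:
        t -= t_i
        t_i *= mult
    return 0.5 * (1.0 + np.cos(np.pi * t / t_i))


# ---------------------------------------------------------------------------
# ReferenceNet: numpy CNN
# ---------------------------------------------------------------------------


class ReferenceNet:
    """Small convolutional classifier with MC-dropout after every weighted layer.

    Architecture for ``input_size`` S (default 64, 640 supported):
    conv3x3(3->8) + ReLU + dropout + maxpool2, conv3x3(8->16) + ReLU +
    dropout + maxpool2, conv3x3(16->32) + ReLU + dropout + maxpool2,
    global average pool, dropout, linear(32->K), softmax.
    """

    CHANNELS = (8, 16, 32)

    def __init__(
        self,
        n_classes: int,
        input_size: int = 64,
        dropout_rate: float = 0.3,
        seed: int = 0,
    ) -> None:
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        if input_size % 8 != 0:
            raise ValueError("input_size must be divisible by 8")
        self.n_classes = n_classes
        self.input_size = input_size
        self.dropout_rate = float(dropout_rate)
        rng = np.random.default_rng(seed)
        c = (3,) + self.CHANNELS
        self.params: dict[str, np.ndarray] = {}
        for i in range(3):
            fan_in = c[i] * 9
            self.params[f"W{i+1}"] = rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, c[i + 1]))
            self.params[f"b{i+1}"] = np.zeros(c[i + 1])
        self.params["W4"] = rng.normal(0, np.sqrt(2.0 / c[-1]), (c[-1], n_classes))
        self.params["b4"] = np.zeros(n_classes)

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward / backward ------------------------------------------------

    def _dropout_mask(self, shape, rng: np.random.Generator | None, dropout: bool) -> np.ndarray | None:
        if not dropout or self.dropout_rate == 0.0:
            return None
        if rng is None:
            raise ValueError("dropout=True requires an rng")
        keep = 1.0 - self.dropout_rate
        return (rng.random(shape) < keep) / keep

    def forward(
        self,
        x: np.ndarray,
        rng: np.random.Generator | None = None,
        dropout: bool = False,
        want_cache: bool = False,
    ):
        """Batch forward pass. x: (N, S, S, 3) normalized floats -> (N, K) probabilities."""
        cache: dict = {"masks": [], "convs": []}
        h = x
        for i in range(3):
            w, b = self.params[f"W{i+1}"], self.params[f"b{i+1}"]
            cols = _im2col3(h)
            z = cols @ w + b
            a = np.maximum(z, 0.0)
            mask = self._dropout_mask(a.shape, rng, dropout)
            if mask is not None:
                a = a * mask
            pooled, pool_idx = _maxpool2(a)
            if want_cache:
                cache["convs"].append((h, cols, z, mask, a, pool_idx))
            h = pooled
        feat = h.mean(axis=(1, 2))  # global average pool
        fmask = self._dropout_mask(feat.shape, rng, dropout)
        feat_d = feat * fmask if fmask is not None else feat
        logits = feat_d @ self.params["W4"] + self.params["b4"]
        probs = _softmax(logits)
        if want_cache:
            cache.update(h_last=h, feat=feat, fmask=fmask, feat_d=feat_d, logits=logits, probs=probs)
            return probs, cache
        return probs

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        grads["W4"] = cache["feat_d"].T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        dfeat = dlogits @ self.params["W4"].T
        if cache["fmask"] is not None:
            dfeat = dfeat * cache["fmask"]
        n, hh, ww, _ = cache["h_last"].shape
        dh = np.broadcast_to(dfeat[:, None, None, :], cache["h_last"].shape) / (hh * ww)
        for i in range(2, -1, -1):
            h_in, cols, z, mask, a, pool_idx = cache["convs"][i]
            da = _maxpool2_backward(dh, a.shape, pool_idx)
            if mask is not None:
                da = da * mask
            dz = da * (z > 0)
            f = dz.shape[-1]
            grads[f"W{i+1}"] = cols.reshape(-1, cols.shape[-1]).T @ dz.reshape(-1, f)
            grads[f"b{i+1}"] = dz.sum(axis=(0, 1, 2))
            if i > 0:
                dh = _col2im3(dz @ self.params[f"W{i+1}"].T, h_in.shape)
        return grads

    # -- contract ----------------------------------------------------------

    def predict_proba(
        self, image: np.ndarray, rng: np.random.Generator | None = None, dropout: bool = False
    ) -> np.ndarray:
        """Single-image stochastic forward pass -> length-K probability vector."""
        if image.shape != (self.input_size, self.input_size, 3):
            raise ValueError(
                f"expected a ({self.input_size}, {self.input_size}, 3) image, got {image.shape}"
            )
        return self.forward(image[None], rng=rng, dropout=dropout)[0]

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = dict(
            n_classes=self.n_classes,
            input_size=self.input_size,
            dropout_rate=self.dropout_rate,
        )
        np.savez(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceNet":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            net = cls(**meta)
            for k in net.params:
                net.params[k] = data[k]
        return net

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in state.items()}


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N,H,W,C) -> (N,H,W,C*9) patches of a padded 3x3 neighbourhood."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # win: (N, H, W, C, 3, 3) -> (N, H, W, C*9)
    return win.reshape(n, h, w, c * 9)


def _col2im3(dcols: np.ndarray, x_shape: tuple) -> np.ndarray:
    """Adjoint of _im2col3: scatter (N,H,W,C*9) gradients back to (N,H,W,C)."""
    n, h, w, c = x_shape
    d = dcols.reshape(n, h, w, c, 3, 3)
    dxp = np.zeros((n, h + 2, w + 2, c))
    for i in range(3):
        for j in range(3):
            dxp[:, i : i + h, j : j + w, :] += d[:, :, :, :, i, j]
    return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


def _maxpool2(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, h, w, c = a.shape
    r = a.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(
        n, h // 2, w // 2, c, 4
    )
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool2_backward(dout: np.ndarray, a_shape: tuple, idx: np.ndarray) -> np.ndarray:
    n, h, w, c = a_shape
    dr = np.zeros((n, h // 2, w // 2, c, 4))
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
    return dr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    best_state: dict[str, np.ndarray]
    best_epoch: int
    best_val_loss: float
    log: list[dict] = field(default_factory=list)  # epoch, train_loss, val_loss, epoch_seconds

    def write_log(self, path: str | Path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["epoch", "train_loss", "val_loss", "epoch_seconds"])
            w.writeheader()
            w.writerows(self.log)


class _AdamW:
    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float):
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr_factor: float):
        self.t += 1
        lr = self.lr * lr_factor
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * params[k])


def _smoothed_targets(labels: np.ndarray, k: int, eps: float) -> np.ndarray:
    q = np.full((len(labels), k), eps / k)
    q[np.arange(len(labels)), labels] += 1.0 - eps
    return q


def load_split_arrays(
    manifest: DatasetManifest, split: str, preprocess_spec: PreprocessSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Load a split's images resized to target size as float [0,1] plus label indices."""
    label_index = {f: i for i, f in enumerate(manifest.vocabulary)}
    sub = manifest.subset(split)
    images = np.stack(
        [resize(r.load_image(manifest.root), preprocess_spec) for r in sub.records]
    ) if len(sub) else np.zeros((0, *preprocess_spec.target_size, 3))
    labels = np.array([label_index[r.family] for r in sub.records], dtype=np.int64)
    return images, labels


def preresize_manifest(manifest: DatasetManifest, spec: PreprocessSpec) -> DatasetManifest:
    """Materialize every record's image at the target size, in memory.

    Useful when one fixture feeds several training runs: the resize is paid
    once instead of once per run. Pixel values are re-quantized to uint8.
    """
    from dataclasses import replace

    records = [
        replace(
            r,
            image_source=(resize(r.load_image(manifest.root), spec) * 255).round().astype(np.uint8),
        )
        for r in manifest.records
    ]
    return DatasetManifest(records=records, vocabulary=manifest.vocabulary)


def train_classifier(
    manifest: DatasetManifest,
    model: ReferenceNet,
    config: TrainConfig = TrainConfig(),
    policy: AugmentationPolicy | None = None,
    preprocess_spec: PreprocessSpec | None = None,
) -> TrainResult:
    """Train on the manifest's train split; checkpoint on minimum validation loss.

    Training images are optionally augmented each epoch with one stochastic
    pass of ``policy`` (CutMix donors are drawn from the training set
    itself), then z-score normalized. Validation loss is computed with
    dropout off and no augmentation. Deterministic given ``config.seed``.
    """
    if config.max_epochs <= 0:
        raise ValueError("max_epochs must be >= 1; nothing would be trained")
    if model.n_classes != len(manifest.vocabulary):
        raise ValueError(
            f"model has {model.n_classes} classes but vocabulary has {len(manifest.vocabulary)}"
        )
    spec = preprocess_spec or PreprocessSpec(target_size=(model.input_size, model.input_size))
    if spec.target_size != (model.input_size, model.input_size):
        raise ValueError("preprocess target size does not match the model input size")

    x_train, y_train = load_split_arrays(manifest, "train", spec)
    x_val, y_val = load_split_arrays(manifest, "validation", spec)
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("manifest must have nonempty train and validation splits")

    means = np.asarray(spec.channel_means)
    stds = np.asarray(spec.channel_stds)
    x_val_n = (x_val - means) / stds

    rng = np.random.default_rng(config.seed)
    opt = _AdamW(model.params, config.learning_rate, config.weight_decay)
    result = TrainResult(best_state=model.state_copy(), best_epoch=-1, best_val_loss=np.inf)
    since_best = 0

    for epoch in range(config.max_epochs):
        t0 = time.perf_counter()
        lr_factor = cosine_warm_restart_factor(epoch, config.restart_period, config.restart_mult)
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_train[idx]
            if policy is not None and policy.steps:
                xb = np.stack(
                    [
                        apply_policy(
                            im,
                            policy,
                            rng,
                            donor=x_train[rng.integers(len(x_train))],
                            stage="train",
                        )
                        for im in xb
                    ]
                )
            xb = (xb - means) / stds
            probs, cache = model.forward(xb, rng=rng, dropout=True, want_cache=True)
            q = _smoothed_targets(y_train[idx], model.n_classes, config.label_smoothing)
            logp = np.log(np.clip(probs, 1e-12, None))
            losses.append(float(-(q * logp).sum(axis=1).mean()))
            dlogits = (probs - q) / len(idx)
            grads = model.backward(cache, dlogits)
            opt.step(model.params, grads, lr_factor)

        val_probs = _batched_forward(model, x_val_n)
        qv = _smoothed_targets(y_val, model.n_classes, config.label_smoothing)
        val_loss = float(-(qv * np.log(np.clip(val_probs, 1e-12, None))).sum(axis=1).mean())
        result.log.append(
            dict(
                epoch=epoch,
                train_loss=float(np.mean(losses)),
                val_loss=val_loss,
                epoch_seconds=time.perf_counter() - t0,
            )
        )
        if val_loss < result.best_val_loss:
            result.best_val_loss = val_loss
            result.best_epoch = epoch
            result.best_state = model.state_copy()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    model.load_state(result.best_state)
    return result


def _batched_forward(model: ReferenceNet, x: np.ndarray, batch: int = 64) -> np.ndarray:
    return np.concatenate(
        [model.forward(x[i : i + batch]) for i in range(0, len(x), batch)]
    )


def evaluate_accuracy(
    model: ReferenceNet, manifest: DatasetManifest, split: str, spec: PreprocessSpec | None = None
) -> float:
    """Deterministic (no dropout, no TTA) top-1 accuracy on a split."""
    spec = spec or PreprocessSpec(target_size=(model.input_size, model.input_size))
    x, y = load_split_arrays(manifest, split, spec)
    if len(x) == 0:
        raise ValueError(f"split {split!r} is empty")
    xn = (x - np.asarray(spec.channel_means)) / np.asarray(spec.channel_stds)
    preds = _batched_forward(model, xn).argmax(axis=1)
    return float((preds == y).mean())
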