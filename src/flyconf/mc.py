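"""Monte Carlo confidence estimation: T stochastic passes, mode, agreement.

Each of the T passes draws a fresh augmentation of the input (test-time
augmentation) and a fresh dropout mask (test-time dropout), takes the
argmax label

    y(t) = argmax_k f_theta(t)(x~),   t = 1..T,

and the final prediction is the mode of {y(1)..y(T)} with confidence the
fraction of passes agreeing with the mode. With all T passes unanimous the
confidence is exactly 1; in general it is bounded below by ceil(T/K)/T.

TTA samples the aleatoric (data) uncertainty, TTD the epistemic (model)
uncertainty; either can be switched off individually to attribute the
spread between the two sources.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .classifier import ClassifierContract
from .manifest import DatasetManifest
from .preprocess import AugmentationPolicy, PolicyError, PreprocessSpec, apply_policy, resize, zscore_normalize

DEFAULT_MC_ITERATIONS = 100


@dataclass(frozen=True)
class MonteCarloResult:
    per_pass_labels: tuple[int, ...]
    final_label: int
    confidence: float
    T: int
    tie_broken: bool
    mean_probs: np.ndarray | None = None  # diagnostic: per-class mean of pass probabilities


def mode_and_confidence(
    labels: Sequence[int], tie_probs: Sequence[float] | None = None
) -> tuple[int, float, bool]:
    """Mode of a label sequence plus the agreement fraction.

    Ties between equally frequent classes are broken by the largest summed
    per-pass probability when ``tie_probs`` is given, otherwise by the
    smallest class index; ``tie_broken`` reports whether a tie occurred.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("cannot take the mode of an empty label sequence")
    counts: dict[int, int] = {}
    for y in labels:
        counts[y] = counts.get(y, 0) + 1
    top = max(counts.values())
    tied = sorted(k for k, v in counts.items() if v == top)
    tie_broken = len(tied) > 1
    if tie_broken and tie_probs is not None:
        probs = np.asarray(tie_probs, dtype=np.float64)
        final = int(max(tied, key=lambda k: (probs[k], -k)))
    else:
        final = tied[0]
    return final, top / len(labels), tie_broken


def _record_seed(seed: int, record_id: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([seed % (2**31), zlib.crc32(record_id.encode("utf-8"))])


def mc_predict(
    model: ClassifierContract,
    image: np.ndarray,
    T: int = DEFAULT_MC_ITERATIONS,
    policy: AugmentationPolicy | None = None,
    preprocess_spec: PreprocessSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    donor_images: Sequence[np.ndarray] | None = None,
    use_dropout: bool = True,
    keep_probs: bool = False,
) -> MonteCarloResult:
    """Run T stochastic forward passes over one image and reduce to a label.

    ``image`` is an 8-bit RGB (or [0,1] float) array of any size; each pass
    resizes it, applies one stochastic draw of the augmentation policy,
    normalizes, and calls the model's stochastic forward with dropout
    enabled. Per-pass rng states are derived from ``seed`` by a counter, so
    passes are independent and the whole call is reproducible.
    ``donor_images`` supplies CutMix counterparts when the policy mixes at
    test time. ``use_dropout=False`` gives the TTA-only (aleatoric)
    diagnostic; an empty policy gives the TTD-only (epistemic) one.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if model.n_classes < 2:
        raise ValueError("model must have at least 2 classes")
    spec = preprocess_spec or PreprocessSpec()
    base = resize(image, spec)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed % (2**31))
    pass_seeds = ss.spawn(T)

    labels: list[int] = []
    prob_sum = np.zeros(model.n_classes)
    for t in range(T):
        rng = np.random.default_rng(pass_seeds[t])
        x = base
        if policy is not None and policy.steps:
            donor = None
            if donor_images is not None and len(donor_images) > 0:
                donor = resize(donor_images[rng.integers(len(donor_images))], spec)
            x = apply_policy(x, policy, rng, donor=donor, stage="test")
        x = zscore_normalize(x, spec)
        probs = np.asarray(model.predict_proba(x, rng=rng, dropout=use_dropout), dtype=np.float64)
        labels.append(int(probs.argmax()))
        prob_sum += probs

    final, confidence, tie_broken = mode_and_confidence(labels, tie_probs=prob_sum)
    return MonteCarloResult(
        per_pass_labels=tuple(labels),
        final_label=final,
        confidence=confidence,
        T=T,
        tie_broken=tie_broken,
        mean_probs=(prob_sum / T) if keep_probs else None,
    )


@dataclass
class BatchPredictions:
    results: list[tuple[str, MonteCarloResult]]
    errors: list[tuple[str, str]] = field(default_factory=list)  # (record_id, message)

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    def write_csv(self, path: str | Path, vocabulary: Sequence[str] | None = None) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["record_id", "final_label", "confidence", "T", "tie_broken"])
            for rid, res in self.results:
                label = vocabulary[res.final_label] if vocabulary else res.final_label
                w.writerow([rid, label, f"{res.confidence:.6f}", res.T, res.tie_broken])


def batch_mc_predict(
    model: ClassifierContract,
    manifest: DatasetManifest,
    T: int = DEFAULT_MC_ITERATIONS,
    policy: AugmentationPolicy | None = None,
    preprocess_spec: PreprocessSpec | None = None,
    seed: int = 0,
    use_dropout: bool = True,
) -> BatchPredictions:
    """One MonteCarloResult per manifest record, in manifest order.

    Per-record seeds derive deterministically from (seed, record_id), so the
    result for a record does not depend on which other records are present.
    Unreadable images are reported per record and the run continues. CutMix
    donors are drawn from the same evaluation set.
    """
    images: dict[str, np.ndarray | None] = {}
    out = BatchPredictions(results=[])
    for rec in manifest.records:
        try:
            images[rec.record_id] = rec.load_image(manifest.root)
        except (FileNotFoundError, OSError) as exc:
            images[rec.record_id] = None
            out.errors.append((rec.record_id, str(exc)))
    donor_pool = [im for im in images.values() if im is not None]
    for rec in manifest.records:
        img = images[rec.record_id]
        if img is None:
            continue
        res = mc_predict(
            model,
            img,
            T=T,
            policy=policy,
            preprocess_spec=preprocess_spec,
            seed=_record_seed(seed, rec.record_id),
            donor_images=donor_pool,
            use_dropout=use_dropout,
        )
        out.results.append((rec.record_id, res))
    return out
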