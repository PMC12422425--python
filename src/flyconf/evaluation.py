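"""Evaluation layer: confusion matrices, OA, Cohen's kappa, comparison aggregates.

Overall accuracy is the trace of the confusion matrix over its total,
OA = (TP + TN) / (TP + TN + FP + FN) in the binary case. Cohen's kappa
corrects agreement for chance, kappa = (po - pe) / (1 - pe), with the
multiclass expected agreement pe = sum_k row_k * col_k / total^2; on 2x2
matrices this reduces exactly to the familiar binary formula.

The model-comparison aggregator averages per-model metrics across the
cropped and uncropped conditions; relative improvement is defined as the
mean of per-model relative increases (not the relative increase of the
means). Per-family confidence summaries restrict to correctly classified
records; paired cropped/uncropped summaries split families into large
(median confidence gain >= 6 percentage points) and small improvement
groups, each ordered by descending gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (K, K); rows = true label, columns = predicted
    vocabulary: tuple[str, ...]

    def __post_init__(self) -> None:
        k = len(self.vocabulary)
        if self.counts.shape != (k, k):
            raise EvaluationError(f"counts shape {self.counts.shape} != ({k}, {k})")
        if (self.counts < 0).any():
            raise EvaluationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_normalized(self) -> np.ndarray:
        """Per-true-family percentage view (rows summing to 100)."""
        rows = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(rows > 0, 100.0 * self.counts / rows, 0.0)

    def write_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["true\\predicted", *self.vocabulary])
            for name, row in zip(self.vocabulary, self.counts):
                w.writerow([name, *row.astype(int)])


def build_confusion(
    truths: Sequence[str], predictions: Sequence[str], vocabulary: Sequence[str]
) -> ConfusionMatrix:
    if len(truths) != len(predictions):
        raise EvaluationError("truths and predictions must have equal length")
    index = {f: i for i, f in enumerate(vocabulary)}
    counts = np.zeros((len(vocabulary), len(vocabulary)), dtype=np.int64)
    for t, p in zip(truths, predictions):
        if t not in index or p not in index:
            raise EvaluationError(f"label outside vocabulary: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, vocabulary=tuple(vocabulary))


def overall_accuracy(confusion: ConfusionMatrix) -> float:
    """Percentage of records on the diagonal."""
    if confusion.total == 0:
        raise EvaluationError("empty confusion matrix")
    return 100.0 * float(np.trace(confusion.counts)) / confusion.total


def cohens_kappa(confusion: ConfusionMatrix) -> float:
    """Chance-corrected agreement (po - pe) / (1 - pe)."""
    n = confusion.total
    if n == 0:
        raise EvaluationError("empty confusion matrix")
    po = float(np.trace(confusion.counts)) / n
    rows = confusion.counts.sum(axis=1)
    cols = confusion.counts.sum(axis=0)
    pe = float((rows * cols).sum()) / (n * n)
    if pe >= 1.0 - 1e-15:
        # all mass in one row/column pair: agreement is perfect or undefined
        if po >= 1.0 - 1e-15:
            return 1.0
        raise EvaluationError("expected agreement pe = 1 with imperfect observed agreement")
    return (po - pe) / (1.0 - pe)


# ---------------------------------------------------------------------------
# Cropped-vs-uncropped model comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelMetrics:
    model: str
    oa: float  # percent
    kappa: float
    mean_confidence: float  # percent


@dataclass
class ComparisonSummary:
    models: list[str]
    uncropped: dict[str, ModelMetrics]
    cropped: dict[str, ModelMetrics]
    absolute_oa_improvements: dict[str, float] = field(default_factory=dict)
    relative_oa_improvements: dict[str, float] = field(default_factory=dict)
    relative_confidence_improvements: dict[str, float] = field(default_factory=dict)
    mean_oa_uncropped: float = 0.0
    mean_oa_cropped: float = 0.0
    mean_kappa_uncropped: float = 0.0
    mean_kappa_cropped: float = 0.0
    mean_confidence_uncropped: float = 0.0
    mean_confidence_cropped: float = 0.0
    mean_relative_oa_improvement: float = 0.0
    mean_relative_confidence_improvement: float = 0.0

    def rounded(self) -> dict:
        """Display view: percentages to 2 decimals, kappa to 4."""
        return {
            "mean_oa_uncropped": round(self.mean_oa_uncropped, 2),
            "mean_oa_cropped": round(self.mean_oa_cropped, 2),
            "mean_kappa_uncropped": round(self.mean_kappa_uncropped, 4),
            "mean_kappa_cropped": round(self.mean_kappa_cropped, 4),
            "mean_confidence_uncropped": round(self.mean_confidence_uncropped, 2),
            "mean_confidence_cropped": round(self.mean_confidence_cropped, 2),
            "mean_relative_oa_improvement": round(self.mean_relative_oa_improvement, 2),
            "mean_relative_confidence_improvement": round(
                self.mean_relative_confidence_improvement, 2
            ),
            "absolute_oa_improvements": {
                m: round(v, 2) for m, v in self.absolute_oa_improvements.items()
            },
        }


def aggregate_model_comparison(rows: Sequence[Mapping]) -> ComparisonSummary:
    """Aggregate per-model metrics across the uncropped and cropped conditions.

    ``rows``: mappings with keys model, cropped (bool), oa, kappa,
    mean_confidence (percent scale for oa/confidence). Both conditions must
    cover the same model set. Full precision is retained internally; use
    :meth:`ComparisonSummary.rounded` for the 2/4-decimal display view.
    """
    uncropped: dict[str, ModelMetrics] = {}
    cropped: dict[str, ModelMetrics] = {}
    for r in rows:
        m = ModelMetrics(r["model"], float(r["oa"]), float(r["kappa"]), float(r["mean_confidence"]))
        (cropped if r["cropped"] else uncropped)[m.model] = m
    if set(uncropped) != set(cropped):
        raise EvaluationError(
            f"model sets differ between conditions: {sorted(uncropped)} vs {sorted(cropped)}"
        )
    if not uncropped:
        raise EvaluationError("no rows to aggregate")
    models = [r["model"] for r in rows if not r["cropped"]]

    s = ComparisonSummary(models=models, uncropped=uncropped, cropped=cropped)
    for m in models:
        u, c = uncropped[m], cropped[m]
        s.absolute_oa_improvements[m] = c.oa - u.oa
        s.relative_oa_improvements[m] = 100.0 * (c.oa - u.oa) / u.oa
        s.relative_confidence_improvements[m] = (
            100.0 * (c.mean_confidence - u.mean_confidence) / u.mean_confidence
        )
    s.mean_oa_uncropped = float(np.mean([uncropped[m].oa for m in models]))
    s.mean_oa_cropped = float(np.mean([cropped[m].oa for m in models]))
    s.mean_kappa_uncropped = float(np.mean([uncropped[m].kappa for m in models]))
    s.mean_kappa_cropped = float(np.mean([cropped[m].kappa for m in models]))
    s.mean_confidence_uncropped = float(np.mean([uncropped[m].mean_confidence for m in models]))
    s.mean_confidence_cropped = float(np.mean([cropped[m].mean_confidence for m in models]))
    s.mean_relative_oa_improvement = float(np.mean(list(s.relative_oa_improvements.values())))
    s.mean_relative_confidence_improvement = float(
        np.mean(list(s.relative_confidence_improvements.values()))
    )
    return s


# ---------------------------------------------------------------------------
# Per-family confidence summaries
# ---------------------------------------------------------------------------

LARGE_IMPROVEMENT_POINTS = 6.0  # median confidence gain, percentage points


@dataclass(frozen=True)
class FamilyConfidence:
    family: str
    n_correct: int
    median: float
    q1: float
    q3: float


def per_family_confidence_summary(
    truths: Sequence[str],
    predictions: Sequence[str],
    confidences: Sequence[float],
    vocabulary: Sequence[str],
) -> dict[str, FamilyConfidence]:
    """Quartiles of confidence per family over correctly classified records only.

    Families with zero correct predictions are absent from the result (they
    are reported as missing, never as zero confidence).
    """
    conf = np.asarray(confidences, dtype=np.float64)
    if ((conf < 0) | (conf > 1)).any():
        raise EvaluationError("confidences must lie in [0, 1]")
    by_family: dict[str, list[float]] = {}
    for t, p, c in zip(truths, predictions, conf):
        if t == p:
            by_family.setdefault(t, []).append(float(c))
    out: dict[str, FamilyConfidence] = {}
    for family in vocabulary:
        vals = by_family.get(family)
        if not vals:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out[family] = FamilyConfidence(family, len(vals), float(med), float(q1), float(q3))
    return out


@dataclass(frozen=True)
class FamilyImprovement:
    family: str
    median_uncropped: float  # percent
    median_cropped: float  # percent
    delta: float  # percentage points
    group: str  # "large" or "small"


def family_improvement_grouping(
    uncropped: Mapping[str, FamilyConfidence],
    cropped: Mapping[str, FamilyConfidence],
) -> list[FamilyImprovement]:
    """Pair per-family medians across conditions; group and order by gain.

    Median confidence deltas of >= 6 percentage points count as large
    improvements and are listed first in descending order, the rest follow
    as small improvements, also descending.
    """
    rows: list[FamilyImprovement] = []
    for family in uncropped:
        if family not in cropped:
            continue
        mu = 100.0 * uncropped[family].median
        mc = 100.0 * cropped[family].median
        delta = mc - mu
        group = "large" if delta >= LARGE_IMPROVEMENT_POINTS else "small"
        rows.append(FamilyImprovement(family, mu, mc, delta, group))
    large = sorted((r for r in rows if r.group == "large"), key=lambda r: -r.delta)
    small = sorted((r for r in rows if r.group == "small"), key=lambda r: -r.delta)
    return large + small


def recommend_taxonomic_level(confidence: float) -> str:
    """Map a prediction confidence to the taxonomic rank worth reporting.

    Confidence >= 0.85: trust the family-level call; below 0.50: keep the
    identification at order level (Diptera); the band in between carries no
    clear action and is flagged for expert review.
    """
    if not 0.0 <= confidence <= 1.0:
        raise EvaluationError(f"confidence {confidence} outside [0, 1]")
    if confidence >= 0.85:
        return "family"
    if confidence < 0.50:
        return "order"
    return "indeterminate"
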