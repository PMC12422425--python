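import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from flyconf import (
    aggregate_model_comparison,
    build_confusion,
    cohens_kappa,
    family_improvement_grouping,
    overall_accuracy,
    per_family_confidence_summary,
    recommend_taxonomic_level,
)
from flyconf.evaluation import ConfusionMatrix, EvaluationError, FamilyConfidence


def _cm(grid, vocab=None):
    grid = np.asarray(grid)
    vocab = vocab or tuple(chr(97 + i) for i in range(len(grid)))
    return ConfusionMatrix(counts=grid, vocabulary=vocab)


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        cm = build_confusion(["a", "b", "a"], ["a", "b", "a"], ["a", "b"])
        np.testing.assert_array_equal(cm.counts, [[2, 0], [0, 1]])

    def test_counting(self):
        cm = build_confusion(["a", "a", "b"], ["a", "b", "b"], ["a", "b"])
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_total_conserved_on_random_pairs(self):
        rng = np.random.default_rng(0)
        vocab = ["a", "b", "c"]
        t = [vocab[i] for i in rng.integers(0, 3, 1000)]
        p = [vocab[i] for i in rng.integers(0, 3, 1000)]
        cm = build_confusion(t, p, vocab)
        assert cm.total == 1000
        np.testing.assert_array_equal(cm.counts.sum(axis=1),
                                      [t.count(v) for v in vocab])

    def test_unknown_label_rejected(self):
        with pytest.raises(EvaluationError):
            build_confusion(["a"], ["z"], ["a", "b"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            build_confusion(["a"], ["a", "b"], ["a", "b"])

    def test_row_normalized_percentages(self):
        cm = _cm([[3, 1], [0, 0]])
        norm = cm.row_normalized()
        np.testing.assert_allclose(norm[0], [75.0, 25.0])
        np.testing.assert_allclose(norm[1], [0.0, 0.0])  # empty row stays zero


class TestOverallAccuracy:
    def test_diagonal_only_is_100(self):
        assert overall_accuracy(_cm([[5, 0], [0, 7]])) == 100.0

    def test_hand_example(self):
        assert overall_accuracy(_cm([[50, 10], [5, 35]])) == pytest.approx(85.0)

    def test_zero_diagonal_is_0(self):
        assert overall_accuracy(_cm([[0, 3], [4, 0]])) == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(EvaluationError):
            overall_accuracy(_cm([[0, 0], [0, 0]]))


class TestKappa:
    def test_perfect_diagonal_kappa_one(self):
        assert cohens_kappa(_cm([[5, 0], [0, 7]])) == pytest.approx(1.0)

    def test_hand_example(self):
        # po = 0.85, pe = (60*55 + 40*45)/100^2 = 0.51, kappa = 0.34/0.49
        assert cohens_kappa(_cm([[50, 10], [5, 35]])) == pytest.approx(0.34 / 0.49)

    def test_independent_labels_kappa_near_zero(self):
        rng = np.random.default_rng(1)
        n = 60_000
        t = rng.integers(0, 4, n)
        p = rng.integers(0, 4, n)
        vocab = ["a", "b", "c", "d"]
        cm = build_confusion([vocab[i] for i in t], [vocab[i] for i in p], vocab)
        assert abs(cohens_kappa(cm)) < 0.02

    def test_matches_sklearn_on_random_multiclass(self):
        rng = np.random.default_rng(2)
        vocab = [f"f{i}" for i in range(7)]
        for _ in range(20):
            t = rng.integers(0, 7, 300)
            p = np.where(rng.random(300) < 0.6, t, rng.integers(0, 7, 300))
            cm = build_confusion([vocab[i] for i in t], [vocab[i] for i in p], vocab)
            assert cohens_kappa(cm) == pytest.approx(cohen_kappa_score(t, p))

    def test_invariance_under_vocabulary_permutation(self):
        rng = np.random.default_rng(3)
        grid = rng.integers(0, 30, (5, 5))
        perm = rng.permutation(5)
        assert cohens_kappa(_cm(grid)) == pytest.approx(
            cohens_kappa(_cm(grid[np.ix_(perm, perm)]))
        )

    def test_degenerate_single_cell_matrices(self):
        # all mass on one diagonal cell: pe = 1 and agreement is perfect
        assert cohens_kappa(_cm([[10, 0], [0, 0]])) == 1.0
        # all mass on one off-diagonal cell: marginals never coincide, pe = 0
        assert cohens_kappa(_cm([[0, 10], [0, 0]])) == 0.0


class TestAggregateComparison:
    def _rows(self):
        return [
            {"model": "m1", "cropped": False, "oa": 80.0, "kappa": 0.8, "mean_confidence": 70.0},
            {"model": "m2", "cropped": False, "oa": 90.0, "kappa": 0.9, "mean_confidence": 80.0},
            {"model": "m1", "cropped": True, "oa": 84.0, "kappa": 0.84, "mean_confidence": 77.0},
            {"model": "m2", "cropped": True, "oa": 93.6, "kappa": 0.95, "mean_confidence": 88.0},
        ]

    def test_identical_conditions_all_deltas_zero(self):
        rows = [
            {"model": "m", "cropped": c, "oa": 88.0, "kappa": 0.88, "mean_confidence": 75.0}
            for c in (False, True)
        ]
        s = aggregate_model_comparison(rows)
        assert s.absolute_oa_improvements["m"] == 0.0
        assert s.mean_relative_oa_improvement == 0.0

    def test_relative_is_mean_of_per_model_ratios(self):
        s = aggregate_model_comparison(self._rows())
        # per-model relative OA: 5% and 4%; mean 4.5 (not 7.6/85*100)
        assert s.mean_relative_oa_improvement == pytest.approx(4.5)
        assert s.absolute_oa_improvements == {"m1": pytest.approx(4.0), "m2": pytest.approx(3.6)}
        assert s.mean_oa_uncropped == pytest.approx(85.0)
        assert s.mean_confidence_cropped == pytest.approx(82.5)

    def test_mismatched_model_sets_rejected(self):
        rows = self._rows()[:3]
        with pytest.raises(EvaluationError):
            aggregate_model_comparison(rows)

    def test_rounded_view_precision(self):
        r = aggregate_model_comparison(self._rows()).rounded()
        assert r["mean_kappa_uncropped"] == round((0.8 + 0.9) / 2, 4)
        assert isinstance(r["mean_oa_cropped"], float)


class TestPerFamilyConfidence:
    def test_all_correct_full_confidence(self):
        t = ["a", "a", "b"]
        summary = per_family_confidence_summary(t, t, [1.0, 1.0, 1.0], ["a", "b"])
        assert summary["a"].median == 1.0 and summary["b"].median == 1.0

    def test_only_correct_records_contribute(self):
        summary = per_family_confidence_summary(
            ["a", "a", "b"], ["a", "b", "b"], [0.9, 0.1, 0.7], ["a", "b"]
        )
        assert summary["a"].n_correct == 1
        assert summary["a"].median == pytest.approx(0.9)

    def test_family_with_zero_correct_reported_missing(self):
        summary = per_family_confidence_summary(["a", "b"], ["b", "b"], [0.5, 0.5], ["a", "b"])
        assert "a" not in summary and "b" in summary

    def test_out_of_range_confidence_rejected(self):
        with pytest.raises(EvaluationError):
            per_family_confidence_summary(["a"], ["a"], [1.4], ["a"])

    def test_grouping_threshold_and_ordering(self):
        def fam(name, med):
            return FamilyConfidence(name, 10, med, med, med)

        unc = {"w": fam("w", 0.80), "x": fam("x", 0.80), "y": fam("y", 0.80), "z": fam("z", 0.80)}
        cro = {"w": fam("w", 0.90), "x": fam("x", 0.89), "y": fam("y", 0.85), "z": fam("z", 0.76)}
        rows = family_improvement_grouping(unc, cro)
        assert [(r.family, r.group) for r in rows] == [
            ("w", "large"), ("x", "large"), ("y", "small"), ("z", "small")
        ]
        assert rows[0].delta == pytest.approx(10.0)
        assert rows[-1].delta == pytest.approx(-4.0)

    def test_exact_six_point_gain_counts_as_large(self):
        unc = {"a": FamilyConfidence("a", 5, 0.84, 0.8, 0.9)}
        cro = {"a": FamilyConfidence("a", 5, 0.90, 0.85, 0.95)}
        assert family_improvement_grouping(unc, cro)[0].group == "large"


class TestTaxonomicLevel:
    @pytest.mark.parametrize(
        "confidence,expected",
        [(0.90, "family"), (0.85, "family"), (0.70, "indeterminate"),
         (0.50, "indeterminate"), (0.49, "order"), (0.30, "order")],
    )
    def test_threshold_rule(self, confidence, expected):
        assert recommend_taxonomic_level(confidence) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(EvaluationError):
            recommend_taxonomic_level(1.2)


class TestBruteForceAgreement:
    def test_oa_and_kappa_match_raw_pair_recomputation(self):
        rng = np.random.default_rng(4)
        vocab = [f"f{i}" for i in range(5)]
        t_idx = rng.integers(0, 5, 400)
        p_idx = np.where(rng.random(400) < 0.7, t_idx, rng.integers(0, 5, 400))
        t = [vocab[i] for i in t_idx]
        p = [vocab[i] for i in p_idx]
        cm = build_confusion(t, p, vocab)
        # brute force from raw pairs
        po = np.mean(t_idx == p_idx)
        pe = sum(
            (np.mean(t_idx == k)) * (np.mean(p_idx == k)) for k in range(5)
        )
        assert overall_accuracy(cm) == pytest.approx(100 * po)
        assert cohens_kappa(cm) == pytest.approx((po - pe) / (1 - pe))
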