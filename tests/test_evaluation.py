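"""Macro-F1 metric and testing-time threshold optimization."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import f1_score

from microloc.evaluation import (
    ConfusionCounts,
    ThresholdVector,
    apply_thresholds,
    confusion_counts,
    default_grid,
    ensemble_average,
    f1_macro,
    greedy_multi_threshold,
    search_single_threshold,
)


class TestConfusionCounts:
    def test_perfect_prediction(self, rng):
        y = rng.random((10, 3)) < 0.4
        counts = confusion_counts(y, y)
        assert (counts.fp == 0).all() and (counts.fn == 0).all()
        assert (counts.tp == y.sum(axis=0)).all()

    def test_complement_prediction_has_no_tp(self, rng):
        y = rng.random((10, 3)) < 0.4
        counts = confusion_counts(y, ~y)
        assert (counts.tp == 0).all()

    def test_hand_tally(self):
        y_true = np.array([[1, 0], [1, 1], [0, 0], [0, 1]])
        y_pred = np.array([[1, 1], [0, 1], [1, 0], [0, 1]])
        counts = confusion_counts(y_true, y_pred)
        assert counts.tp.tolist() == [1, 2]
        assert counts.fp.tolist() == [1, 1]
        assert counts.fn.tolist() == [1, 0]

    def test_additive_over_sample_blocks(self, rng):
        y = rng.random((20, 4)) < 0.5
        p = rng.random((20, 4)) < 0.5
        whole = confusion_counts(y, p)
        parts = confusion_counts(y[:11], p[:11]) + confusion_counts(y[11:], p[11:])
        assert (whole.tp == parts.tp).all()
        assert (whole.fp == parts.fp).all()
        assert (whole.fn == parts.fn).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((3, 2)), np.zeros((2, 3)))


class TestF1Macro:
    def test_perfect_is_one(self, rng):
        y = rng.random((10, 4)) < 0.5
        assert f1_macro(confusion_counts(y, y)).macro == 1.0

    def test_single_class_hand_value(self):
        report = f1_macro(ConfusionCounts(tp=[1], fp=[1], fn=[1]))
        assert report.precision[0] == report.recall[0] == 0.5
        assert report.f1[0] == 0.5

    def test_macro_is_unweighted_mean(self):
        # one perfect class, one all-wrong class
        report = f1_macro(ConfusionCounts(tp=[5, 0], fp=[0, 3], fn=[0, 2]))
        assert report.f1.tolist() == [1.0, 0.0]
        assert report.macro == 0.5

    def test_zero_support_class_scores_zero_but_counts(self):
        report = f1_macro(ConfusionCounts(tp=[3, 0], fp=[0, 0], fn=[0, 0]))
        assert report.f1[1] == 0.0
        assert report.macro == 0.5

    def test_agrees_with_sklearn_on_random_matrices(self, rng):
        """Independent oracle: scikit-learn's macro F1 on 100 random
        small problems, agreement to 1e-12."""
        for _ in range(100):
            n, c = int(rng.integers(2, 12)), int(rng.integers(2, 6))
            y_true = rng.random((n, c)) < 0.5
            y_pred = rng.random((n, c)) < 0.5
            ours = f1_macro(confusion_counts(y_true, y_pred)).macro
            ref = f1_score(y_true, y_pred, average="macro", zero_division=0)
            assert abs(ours - ref) < 1e-12


class TestSingleThreshold:
    def test_grid_has_17_values(self):
        assert len(default_grid()) == 17
        assert default_grid()[0] == 0.1 and default_grid()[-1] == 0.9

    def test_separable_probs_tie_break_to_lowest(self, rng):
        y = rng.random((20, 3)) < 0.5
        probs = y.astype(float) * 0.98 + 0.01
        t, score = search_single_threshold(probs, y)
        assert score == 1.0
        assert t == 0.1  # every grid value is perfect; lower wins

    def test_constructed_optimum_is_recovered(self, rng):
        """Probabilities built so exhaustive grid evaluation peaks at
        0.3: negatives fill [0.1, 0.29] (lower thresholds admit false
        positives), positives fill [0.3, 0.9] (higher thresholds lose
        true positives)."""
        n = 200
        y = np.zeros((n, 2), dtype=bool)
        y[::2] = True
        probs = np.where(y, rng.uniform(0.3, 0.9, (n, 2)), rng.uniform(0.1, 0.29, (n, 2)))
        t, score = search_single_threshold(probs, y)
        # independent exhaustive evaluation
        best = max(
            default_grid(),
            key=lambda g: f1_macro(confusion_counts(y, probs >= g)).macro,
        )
        assert t == pytest.approx(best)
        assert t == pytest.approx(0.3)

    def test_permutation_invariance(self, rng):
        y = rng.random((50, 4)) < 0.3
        probs = rng.random((50, 4))
        perm = rng.permutation(50)
        assert search_single_threshold(probs, y) == search_single_threshold(
            probs[perm], y[perm]
        )

    def test_threshold_comparison_is_closed_lower_bound(self):
        probs = np.array([[0.3, 0.7]])
        pred = apply_thresholds(probs, ThresholdVector(np.array([0.3, 0.71])))
        assert pred.tolist() == [[True, False]]


class TestGreedyMultiThreshold:
    def test_separated_probs_keep_init(self, rng):
        y = rng.random((30, 3)) < 0.5
        probs = y.astype(float) * 0.9 + 0.05
        vec, trace = greedy_multi_threshold(probs, y, init_threshold=0.3)
        assert np.allclose(vec.thresholds, 0.3)
        assert np.allclose(trace, 1.0)

    def test_recovers_distinct_per_class_optima(self, rng):
        """Two classes whose optima differ (0.2 and 0.6): the greedy
        pass must match the exhaustive 17x17 grid search."""
        n = 300
        y = rng.random((n, 2)) < np.array([0.5, 0.5])
        probs = np.empty((n, 2))
        # class 0: positives >= 0.2, negatives < 0.2 -> optimum 0.2
        probs[:, 0] = np.where(y[:, 0], rng.uniform(0.2, 0.5, n), rng.uniform(0.0, 0.19, n))
        # class 1: positives >= 0.6, negatives < 0.6 -> optimum 0.6
        probs[:, 1] = np.where(y[:, 1], rng.uniform(0.6, 0.95, n), rng.uniform(0.0, 0.59, n))
        vec, trace = greedy_multi_threshold(probs, y, init_threshold=0.4)
        grid = default_grid()
        best = max(
            itertools.product(grid, grid),
            key=lambda ts: f1_macro(confusion_counts(y, probs >= np.array(ts))).macro,
        )
        best_score = f1_macro(confusion_counts(y, probs >= np.array(best))).macro
        assert trace[-1] == pytest.approx(best_score)
        assert f1_macro(confusion_counts(y, probs >= vec.thresholds)).macro == pytest.approx(
            best_score
        )

    def test_trace_non_decreasing_on_random_instances(self, rng):
        for _ in range(200):
            n, c = int(rng.integers(5, 25)), int(rng.integers(2, 6))
            y = rng.random((n, c)) < 0.4
            probs = rng.random((n, c))
            _, trace = greedy_multi_threshold(probs, y, init_threshold=0.3)
            assert (np.diff(trace) >= -1e-15).all()

    def test_final_score_at_least_init_score(self, rng):
        y = rng.random((40, 5)) < 0.3
        probs = rng.random((40, 5))
        _, trace = greedy_multi_threshold(probs, y, init_threshold=0.5)
        assert trace[-1] >= trace[0]

    def test_zero_support_class_keeps_init(self, rng):
        y = np.zeros((20, 2), dtype=bool)
        y[:, 0] = rng.random(20) < 0.5
        probs = rng.random((20, 2))
        vec, _ = greedy_multi_threshold(probs, y, init_threshold=0.35)
        assert vec.thresholds[1] == 0.35

    def test_invalid_init_rejected(self, rng):
        with pytest.raises(ValueError):
            greedy_multi_threshold(rng.random((5, 2)), np.ones((5, 2)), init_threshold=1.5)


class TestEnsemble:
    def test_single_matrix_identity(self, rng):
        m = rng.random((5, 3))
        assert np.array_equal(ensemble_average([m]), m)

    def test_complementary_pair_averages_to_half(self, rng):
        m = rng.random((5, 3))
        assert np.allclose(ensemble_average([m, 1 - m]), 0.5)

    def test_identical_matrices_unchanged(self, rng):
        m = rng.random((4, 2))
        assert np.allclose(ensemble_average([m, m.copy(), m.copy()]), m)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ensemble_average([rng.random((3, 2)), rng.random((2, 3))])

    def test_id_ordering_mismatch_rejected(self, rng):
        m = rng.random((2, 2))
        with pytest.raises(ValueError):
            ensemble_average([m, m], ids=[["a", "b"], ["b", "a"]])
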