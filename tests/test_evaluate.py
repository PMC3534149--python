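"""Confusion counts, precision-recall curves and replicate MAD."""

import itertools

import numpy as np
import pandas as pd
import pytest

from celstain import (FlagMask, NoiseScoreGrid, SpikeGroundTruth, confusion_counts,
                      mad_from_diagonal, pr_curve, precision_at_recall)


def truth_on_row(spiked_cols, n_cols):
    xy = np.array([[c, 0] for c in spiked_cols], dtype=int).reshape(-1, 2)
    return SpikeGroundTruth(1, n_cols, xy, np.full(len(spiked_cols), 850.0))


def mask_on_row(flag_cols, n_cols):
    m = np.zeros((1, n_cols), dtype=bool)
    m[0, list(flag_cols)] = True
    return FlagMask(m)


def scores_on_row(values):
    return NoiseScoreGrid(np.atleast_2d(np.asarray(values, dtype=float)), kind="fc")


ALL = np.ones((1, 10), dtype=bool)


class TestConfusionCounts:
    def test_direct_count(self):
        truth = truth_on_row([0, 1, 2], 10)
        mask = mask_on_row([0, 1, 2, 3], 10)
        c = confusion_counts(mask, truth, ALL)
        assert (c.TP, c.FP, c.FN, c.TN) == (3, 1, 0, 6)
        assert c.n == 10

    def test_empty_mask(self):
        truth = truth_on_row([0, 1, 2], 10)
        c = confusion_counts(mask_on_row([], 10), truth, ALL)
        assert (c.TP, c.FP, c.FN) == (0, 0, 3)

    def test_perfect_detector(self):
        truth = truth_on_row([4, 7], 10)
        c = confusion_counts(mask_on_row([4, 7], 10), truth, ALL)
        assert c.FP == 0 and c.FN == 0

    def test_universe_restriction(self):
        truth = truth_on_row([0], 10)
        u = np.zeros((1, 10), dtype=bool)
        u[0, :5] = True
        c = confusion_counts(mask_on_row([0, 7], 10), truth, u)
        assert (c.TP, c.FP, c.TN, c.FN) == (1, 0, 4, 0)  # probe 7 outside universe

    def test_dimension_mismatch_rejected(self):
        truth = truth_on_row([0], 10)
        with pytest.raises(ValueError):
            confusion_counts(mask_on_row([0], 9), truth, ALL)

    def test_brute_force_formula_equivalence(self):
        """Eqs for precision/recall hold against enumeration over every flag
        subset of a 6-probe universe."""
        n = 6
        u = np.ones((1, n), dtype=bool)
        truth = truth_on_row([1, 3, 4], n)
        spiked = {1, 3, 4}
        for r in range(n + 1):
            for subset in itertools.combinations(range(n), r):
                c = confusion_counts(mask_on_row(subset, n), truth, u)
                tp = len(spiked & set(subset))
                fp = len(set(subset) - spiked)
                fn = len(spiked - set(subset))
                tn = n - tp - fp - fn
                assert (c.TP, c.FP, c.FN, c.TN) == (tp, fp, fn, tn)
                if subset:
                    assert c.precision == pytest.approx(tp / (tp + fp))
                assert c.recall == pytest.approx(tp / (tp + fn))


class TestPRCurve:
    def test_hand_enumerated_points(self):
        scores = scores_on_row([3, 2, 1])
        truth = truth_on_row([0, 1], 3)
        curve = pr_curve(scores, truth, np.ones((1, 3), dtype=bool))
        expect = [(3, 0.5, 1.0), (2, 1.0, 1.0), (1, 1.0, 2 / 3)]
        np.testing.assert_allclose(curve.points.to_numpy(), expect)
        assert curve.positive_count == 2

    def test_all_spiked_precision_one(self):
        scores = scores_on_row([5, 1, 3])
        truth = truth_on_row([0, 1, 2], 3)
        curve = pr_curve(scores, truth, np.ones((1, 3), dtype=bool))
        assert np.all(curve.points["precision"] == 1.0)

    def test_no_positives_rejected(self):
        scores = scores_on_row([1, 2])
        truth = truth_on_row([], 2)
        with pytest.raises(ValueError, match="recall undefined"):
            pr_curve(scores, truth, np.ones((1, 2), dtype=bool))

    def test_ties_enter_together(self):
        scores = scores_on_row([2, 2, 1, 1])
        truth = truth_on_row([0, 1], 4)
        curve = pr_curve(scores, truth, np.ones((1, 4), dtype=bool))
        assert len(curve.points) == 2
        np.testing.assert_allclose(curve.points["recall"], [1.0, 1.0])
        np.testing.assert_allclose(curve.points["precision"], [1.0, 0.5])

    def test_recall_non_decreasing_random(self):
        rng = np.random.default_rng(0)
        scores = NoiseScoreGrid(rng.normal(size=(8, 8)) ** 2, kind="fc")
        m = rng.random((8, 8)) < 0.2
        ys, xs = np.nonzero(m)
        truth = SpikeGroundTruth(8, 8, np.column_stack([xs, ys]), np.ones(m.sum()))
        curve = pr_curve(scores, truth, np.ones((8, 8), dtype=bool))
        assert np.all(np.diff(curve.points["recall"]) >= 0)

    def test_matches_subset_enumeration_on_6_probes(self):
        """Every PR point equals the confusion-count evaluation of the
        corresponding threshold flag set (brute-force oracle)."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            s = np.round(rng.uniform(0, 3, size=6), 1)  # rounded to force ties
            spiked_cols = list(np.nonzero(rng.random(6) < 0.5)[0])
            if not spiked_cols:
                spiked_cols = [0]
            scores = scores_on_row(s)
            truth = truth_on_row(spiked_cols, 6)
            u = np.ones((1, 6), dtype=bool)
            curve = pr_curve(scores, truth, u)
            for _, row in curve.points.iterrows():
                mask = mask_on_row(list(np.nonzero(s >= row["threshold"])[0]), 6)
                c = confusion_counts(mask, truth, u)
                assert c.recall == pytest.approx(row["recall"])
                assert c.precision == pytest.approx(row["precision"])


class TestPrecisionAtRecall:
    def _curve(self):
        scores = scores_on_row([3, 2, 1])
        truth = truth_on_row([0, 1], 3)
        return pr_curve(scores, truth, np.ones((1, 3), dtype=bool))

    def test_separating_scores_give_one(self):
        scores = scores_on_row([9, 8, 1, 2])
        truth = truth_on_row([0, 1], 4)
        curve = pr_curve(scores, truth, np.ones((1, 4), dtype=bool))
        for target in (0.2, 0.5, 0.85, 1.0):
            assert precision_at_recall(curve, target) == 1.0

    def test_read_from_enumerated_curve(self):
        assert precision_at_recall(self._curve(), 0.85) == 1.0
        assert precision_at_recall(self._curve(), 0.4) == 1.0

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            precision_at_recall(self._curve(), 0.0)


class TestMadFromDiagonal:
    def test_examples(self):
        a = pd.Series([1.0, 2.0], index=["P1", "P2"])
        assert mad_from_diagonal(a, a) == 0.0
        assert mad_from_diagonal(a, a + 2) == 2.0
        b = pd.Series([0.0, 3.0], index=["P1", "P2"])
        assert mad_from_diagonal(pd.Series([0.0, 1.0], index=["P1", "P2"]), b) == 1.0

    def test_exclusion_and_empty_intersection(self):
        a = pd.Series([1.0, 5.0], index=["P1", "P2"])
        b = pd.Series([1.0, 0.0], index=["P1", "P2"])
        assert mad_from_diagonal(a, b, exclude=["P2"]) == 0.0
        with pytest.raises(ValueError, match="no shared"):
            mad_from_diagonal(a, pd.Series([1.0], index=["P9"]))

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(2)
        idx = [f"P{i}" for i in range(50)]
        a, b, c = (pd.Series(rng.normal(size=50), index=idx) for _ in range(3))
        assert mad_from_diagonal(a, b) == pytest.approx(mad_from_diagonal(b, a))
        assert mad_from_diagonal(a, c) <= (mad_from_diagonal(a, b)
                                           + mad_from_diagonal(b, c) + 1e-12)
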