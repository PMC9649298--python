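"""Confusion counting, the ACC/SE/SP/F1 formulas and ROC/AUC.

AUC is validated against the exhaustive pairwise ranking statistic
P(score_pos > score_neg) + 0.5 P(tie) by brute-force pair counting.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcunet.metrics import (ConfusionCounts, accuracy, aggregate,
                            confusion_counts, f1_score, report_csv,
                            report_text, roc_auc, sensitivity, specificity)


def pairwise_auc_oracle(scores, truth):
    """Count every (positive, negative) pair; ties score one half."""
    pos = scores[truth.astype(bool)]
    neg = scores[~truth.astype(bool)]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestConfusionCounts:
    def test_perfect_prediction(self, rng):
        truth = (rng.random((10, 10)) > 0.6).astype(int)
        c = confusion_counts(truth, truth)
        assert c.fp == 0 and c.fn == 0
        assert c.tp == truth.sum() and c.tn == (1 - truth).sum()

    def test_degenerate_all_positive_prediction(self):
        c = confusion_counts(np.ones((10, 10), int), np.zeros((10, 10), int),
                             np.ones((10, 10), int))
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 100, 0)

    def test_worked_4x4_grid_with_partial_fov(self):
        truth = np.zeros((4, 4), int)
        truth[0, :3] = 1
        truth[1, :2] = 1              # 5 positives
        pred = np.zeros((4, 4), int)
        pred[0, :3] = 1               # 3 hits
        pred[2, 2] = 1
        pred[3, 0] = 1                # 2 false alarms
        fov = np.ones((4, 4), int)
        fov[3, 3] = 0                 # corner excluded
        c = confusion_counts(pred, truth, fov)
        assert (c.tp, c.fn, c.fp, c.tn) == (3, 2, 2, 8)
        # exhaustive per-pixel enumeration over the FOV
        tp = sum(pred[i, j] and truth[i, j]
                 for i in range(4) for j in range(4) if fov[i, j])
        assert c.tp == tp
        assert c.total == fov.sum()

    def test_shape_and_binary_validation(self):
        with pytest.raises(ValueError, match="shape"):
            confusion_counts(np.zeros((2, 2), int), np.zeros((3, 3), int))
        with pytest.raises(ValueError, match="binary"):
            confusion_counts(np.full((2, 2), 2), np.zeros((2, 2), int))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_counts_conserved_over_fov(self, seed):
        r = np.random.default_rng(seed)
        pred = (r.random((8, 8)) > 0.5).astype(int)
        truth = (r.random((8, 8)) > 0.7).astype(int)
        fov = (r.random((8, 8)) > 0.2).astype(int)
        c = confusion_counts(pred, truth, fov)
        assert c.total == fov.sum()
        assert c.tp + c.fn == truth[fov.astype(bool)].sum()


class TestFormulas:
    def test_worked_example(self):
        c = ConfusionCounts(tp=8, fn=2, tn=85, fp=5)
        assert accuracy(c) == pytest.approx(0.93)
        assert sensitivity(c) == pytest.approx(0.8)
        assert specificity(c) == pytest.approx(85 / 90)

    def test_perfect_counts(self):
        c = ConfusionCounts(tp=10, tn=90)
        assert accuracy(c) == sensitivity(c) == specificity(c) == 1.0
        assert f1_score(c) == 1.0

    def test_f1_worked_example(self):
        assert f1_score(ConfusionCounts(tp=8, fn=2, fp=5)) == pytest.approx(16 / 23)

    def test_degenerate_denominators_warn_and_return_zero(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert sensitivity(ConfusionCounts(tn=5)) == 0.0
        with pytest.warns(RuntimeWarning):
            assert f1_score(ConfusionCounts(tn=5)) == 0.0

    @given(st.tuples(st.integers(0, 500), st.integers(0, 500),
                     st.integers(0, 500), st.integers(0, 500)))
    @settings(max_examples=100, deadline=None)
    def test_accuracy_identity(self, counts):
        """ACC = (SE*P + SP*N) / (P + N) whenever all terms are defined."""
        tp, tn, fp, fn = counts
        c = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
        P, N = tp + fn, tn + fp
        if P == 0 or N == 0:
            return
        lhs = accuracy(c)
        rhs = (sensitivity(c) * P + specificity(c) * N) / (P + N)
        assert lhs == pytest.approx(rhs, abs=1e-12)
        for v in (lhs, sensitivity(c), specificity(c), f1_score(c)):
            assert 0.0 <= v <= 1.0


class TestROCAUC:
    def test_all_ties_give_half(self):
        truth = np.array([1, 1, 0, 0])
        _, auc = roc_auc(np.full(4, 0.5), truth)
        assert auc == pytest.approx(0.5)

    def test_perfect_separation_gives_one(self):
        truth = np.array([1, 1, 0, 0])
        _, auc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), truth)
        assert auc == pytest.approx(1.0)

    def test_worked_six_pixel_example(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        truth = np.array([1, 1, 0, 1, 0, 0])
        # pairs: positives {0.9, 0.8, 0.6} vs negatives {0.7, 0.5, 0.4}
        # -> 3 + 3 + 2 = 8 wins of 9 pairs, no ties
        _, auc = roc_auc(scores, truth)
        assert auc == pytest.approx(8 / 9)
        assert auc == pytest.approx(pairwise_auc_oracle(scores, truth))

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.random(200)
        truth = (rng.random(200) > 0.7).astype(int)
        curve, _ = roc_auc(scores, truth)
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_trapezoid_equals_pairwise_statistic(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            truth = (rng.random(n) > 0.5).astype(int)
            if truth.all() or not truth.any():
                continue
            _, auc = roc_auc(scores, truth)
            assert auc == pytest.approx(pairwise_auc_oracle(scores, truth),
                                        abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="single class"):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_permutation_invariance(self, rng):
        scores = rng.random(100)
        truth = (rng.random(100) > 0.6).astype(int)
        perm = rng.permutation(100)
        _, a = roc_auc(scores, truth)
        _, b = roc_auc(scores[perm], truth[perm])
        assert a == pytest.approx(b, abs=1e-12)


class TestAggregation:
    def _items(self, rng, n=3):
        items = []
        for _ in range(n):
            scores = rng.random((16, 16))
            truth = (rng.random((16, 16)) > 0.7).astype(int)
            fov = np.ones((16, 16), int)
            fov[0, 0] = 0
            items.append((scores, truth, fov))
        return items

    def test_pooled_matches_manual_global_counts(self, rng):
        items = self._items(rng)
        row = aggregate(items, mode="pooled", threshold=0.5)
        total = sum(ConfusionCounts().total for _ in items)
        pooled = ConfusionCounts()
        for s, t, f in items:
            pooled = pooled + confusion_counts(s >= 0.5, t, f)
        assert row["ACC"] == pytest.approx(accuracy(pooled))
        assert row["n_pixels"] == pooled.total

    def test_per_image_mode_differs_but_bounded(self, rng):
        items = self._items(rng)
        row = aggregate(items, mode="per_image")
        for col in ("ACC", "SEN", "SP", "AUC", "F1"):
            assert 0.0 <= row[col] <= 1.0

    def test_report_writers(self, rng, tmp_path):
        row = aggregate(self._items(rng))
        text = report_text({"synthetic": row})
        assert "synthetic" in text and "ACC" in text
        csv_text = report_csv({"synthetic": row}, tmp_path / "report.csv")
        assert (tmp_path / "report.csv").read_text() == csv_text
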