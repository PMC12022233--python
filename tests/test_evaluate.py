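import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myodx.ensemble import softmax
from myodx.evaluate import (
    balanced_accuracy,
    class_weights,
    confusion,
    metrics_report,
    ovo_prc,
    ovr_curves,
    weighted_topn,
)


def random_predictions(rng, n, k):
    proba = softmax(rng.normal(size=(n, k)) * 2)
    y = rng.integers(0, k, size=n)
    return np.array([f"c{i}" for i in y]), proba, [f"c{i}" for i in range(k)]


class TestClassWeights:
    def test_inverse_frequency(self):
        w = class_weights(["A", "A", "A", "B"])
        assert w["A"] == pytest.approx(4 / 3)
        assert w["B"] == pytest.approx(4.0)

    def test_balanced_labels_weight_equals_k(self):
        w = class_weights(["A", "B", "C"] * 5)
        assert all(v == pytest.approx(3.0) for v in w.values())

    def test_single_class_weight_is_one(self):
        assert class_weights(["A"] * 7)["A"] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            class_weights([])


class TestWeightedTopN:
    def test_worked_example(self):
        """Labels [A,A,A,B], top-1 hits on two A's and the B: W1 = 5/6,
        matching balanced accuracy (2/3 + 1) / 2 computed independently."""
        y = np.array(["A", "A", "A", "B"])
        proba = np.array([[0.9, 0.1],
                          [0.8, 0.2],
                          [0.3, 0.7],   # the missed A
                          [0.2, 0.8]])
        w1 = weighted_topn(y, proba, 1, classes=["A", "B"])
        assert w1 == pytest.approx(5 / 6)
        y_pred = np.array(["A", "B"])[np.argmax(proba, axis=1)]
        assert balanced_accuracy(y, y_pred) == pytest.approx(5 / 6)

    def test_full_ranking_always_hits(self, rng):
        y, proba, classes = random_predictions(rng, 50, 6)
        assert weighted_topn(y, proba, 6, classes) == 1.0

    def test_n_beyond_class_count_rejected(self, rng):
        y, proba, classes = random_predictions(rng, 10, 3)
        with pytest.raises(ValueError):
            weighted_topn(y, proba, 4, classes)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_w1_equals_balanced_accuracy(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        y, proba, classes = random_predictions(rng, int(rng.integers(20, 80)), k)
        while len(np.unique(y)) < k:  # every class must occur
            y, proba, classes = random_predictions(rng, 80, k)
        w1 = weighted_topn(y, proba, 1, classes)
        y_pred = np.array(classes)[np.argmax(proba, axis=1)]
        assert w1 == pytest.approx(balanced_accuracy(y, y_pred), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_n(self, seed):
        rng = np.random.default_rng(seed)
        y, proba, classes = random_predictions(rng, 60, 5)
        values = [weighted_topn(y, proba, n, classes) for n in range(1, 6)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] == 1.0

    def test_invariant_to_duplicating_one_class(self, rng):
        y, proba, classes = random_predictions(rng, 60, 4)
        base = weighted_topn(y, proba, 2, classes)
        dup = y == "c1"
        y2 = np.concatenate([y, y[dup]])
        proba2 = np.vstack([proba, proba[dup]])
        assert weighted_topn(y2, proba2, 2, classes) == pytest.approx(base)


class TestBalancedAccuracy:
    def test_perfect_is_one(self):
        y = ["a", "b", "a", "c"]
        assert balanced_accuracy(y, y) == 1.0

    def test_constant_predictor_two_classes(self):
        y = ["a"] * 9 + ["b"]
        assert balanced_accuracy(y, ["a"] * 10) == pytest.approx(0.5)


class TestConfusion:
    def test_perfect_is_identity_after_normalization(self):
        y = np.array(["a", "b", "c", "a"])
        mat, classes = confusion(y, y, normalize="truth")
        assert np.array_equal(mat, np.eye(3))

    def test_rows_sum_to_one(self, rng):
        y, proba, classes = random_predictions(rng, 100, 5)
        y_pred = np.array(classes)[np.argmax(proba, axis=1)]
        mat, _ = confusion(y, y_pred, normalize="truth")
        assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12)

    def test_hand_counted_two_class(self):
        y_true = ["a", "a", "a", "b", "b"]
        y_pred = ["a", "b", "a", "b", "a"]
        mat, classes = confusion(y_true, y_pred)
        assert mat.tolist() == [[2, 1], [1, 1]]
        assert mat.sum() == 5


class TestOvrCurves:
    def test_perfect_separation(self):
        y = np.array(["a", "a", "b", "b"])
        proba = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        out = ovr_curves(y, proba, ["a", "b"])
        for c in ("a", "b"):
            assert out["per_class"][c]["auroc"] == 1.0
            assert out["per_class"][c]["auprc"] == 1.0
        assert out["micro"]["auroc"] == 1.0 and out["macro"]["auprc"] == 1.0

    def test_single_positive_ranked_first(self):
        y = np.array(["a", "b", "b", "b"])
        proba = np.array([[0.9, 0.1], [0.1, 0.9], [0.2, 0.8], [0.3, 0.7]])
        out = ovr_curves(y, proba, ["a", "b"])
        assert out["per_class"]["a"]["auprc"] == 1.0

    def test_random_scores_near_half_auroc(self):
        rng = np.random.default_rng(0)
        n = 4000
        y = np.where(rng.random(n) < 0.5, "a", "b")
        p = rng.random(n)
        proba = np.column_stack([p, 1 - p])
        out = ovr_curves(y, proba, ["a", "b"])
        assert out["per_class"]["a"]["auroc"] == pytest.approx(0.5, abs=0.05)

    def test_class_without_positives_skipped(self):
        y = np.array(["a", "a", "b"])
        proba = np.full((3, 3), 1 / 3)
        with pytest.warns(UserWarning, match="no positive"):
            out = ovr_curves(y, proba, ["a", "b", "c"])
        assert "c" not in out["per_class"]


class TestOvoPrc:
    def test_separable_pair_is_one_and_symmetric(self):
        y = np.array(["a", "a", "b", "b", "c"])
        proba = np.array([[0.8, 0.1, 0.1],
                          [0.7, 0.2, 0.1],
                          [0.1, 0.8, 0.1],
                          [0.2, 0.7, 0.1],
                          [0.1, 0.1, 0.8]])
        mat = ovo_prc(y, proba, ["a", "b", "c"])
        assert mat[0, 1] == 1.0
        assert np.allclose(mat, mat.T, equal_nan=True)
        assert np.isnan(mat[0, 0])

    def test_hand_worked_pair(self):
        """4-sample pair, scores renormalized over the pair; AUPRC by
        explicit threshold enumeration.

        Positive class a, scores for a: (0.9, 0.4, 0.6, 0.1), truth
        (a, a, b, b).  Descending-score sweep gives precision/recall points
        (1, 1/2), (1/2, 1/2), (2/3, 1) -> stepwise area = 1/2 * 1 + ... ;
        direction b is symmetric with the same area here.
        """
        y = np.array(["a", "a", "b", "b"])
        pa = np.array([0.9, 0.4, 0.6, 0.1])
        proba = np.column_stack([pa, 1 - pa])
        # oracle: enumerate thresholds on the renormalized (identical) scores
        def auprc(y_bin, s):
            order = np.argsort(-s, kind="stable")
            tp = fp = 0
            pos = y_bin.sum()
            pts = []
            for i in order:
                if y_bin[i]:
                    tp += 1
                else:
                    fp += 1
                pts.append((tp / (tp + fp), tp / pos))
            area, prev_r = 0.0, 0.0
            for prec, rec in pts:
                area += prec * (rec - prev_r)
                prev_r = rec
            return area
        want = 0.5 * (auprc((y == "a").astype(int), pa)
                      + auprc((y == "b").astype(int), 1 - pa))
        mat = ovo_prc(y, proba, ["a", "b"])
        assert mat[0, 1] == pytest.approx(want, abs=1e-12)


class TestMetricsReport:
    def test_report_fields_consistent(self, rng):
        y, proba, classes = random_predictions(rng, 120, 4)
        rep = metrics_report(y, proba, classes)
        assert rep["weighted_topn"]["W1"] == pytest.approx(
            rep["balanced_accuracy"], abs=1e-12)
        assert 0 <= rep["auprc_micro"] <= 1
        rows = np.array(rep["confusion_truth_normalized"])
        assert np.allclose(rows.sum(axis=1), 1.0)
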