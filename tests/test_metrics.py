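"""Metric formulas against hand arithmetic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdcnn_ecg import metrics as mx


def brute_force_kappa(y_true, y_pred):
    """Direct contingency-table kappa, independent of the implementation."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    n = y_true.size
    classes = sorted(set(y_true) | set(y_pred))
    po = sum(t == p for t, p in zip(y_true, y_pred)) / n
    pe = sum(
        (y_true == c).sum() * (y_pred == c).sum() for c in classes
    ) / n**2
    if pe >= 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def brute_force_auc(pos_scores, neg_scores):
    """Pair-counting AUC: wins + half-ties over all pos-neg pairs."""
    wins = 0.0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 1, 2, 2, 1, 0])
        cm = mx.confusion_matrix(y, y, 3)
        assert np.array_equal(cm, np.diag([2, 2, 2]))

    def test_enumerated_two_class_case(self):
        cm = mx.confusion_matrix([0, 0, 1, 1], [0, 1, 0, 1], 2)
        assert np.array_equal(cm, [[1, 1], [1, 1]])

    def test_marginals_equal_class_counts(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        cm = mx.confusion_matrix(y_true, y_pred, 4)
        assert np.array_equal(cm.sum(axis=1), np.bincount(y_true, minlength=4))
        assert np.array_equal(cm.sum(axis=0), np.bincount(y_pred, minlength=4))

    def test_length_mismatch_rejected(self):
        with pytest.raises(mx.PairingError):
            mx.confusion_matrix([0, 1], [0], 2)


class TestBinaryRates:
    def test_worked_case(self):
        # TP=3, TN=4, FP=2, FN=1
        cm = np.array([[3, 1], [2, 4]])
        r = mx.binary_rates(cm, 0)
        assert (r.tp, r.tn, r.fp, r.fn) == (3, 4, 2, 1)
        assert r.accuracy == pytest.approx(0.7)
        assert r.sensitivity == pytest.approx(0.75)
        assert r.specificity == pytest.approx(2 / 3)
        assert r.precision == pytest.approx(0.6)
        assert r.recall == r.sensitivity
        assert r.f1 == pytest.approx(2 / 3)

    def test_perfect_class(self):
        r = mx.binary_rates(np.diag([5, 7]), 0)
        assert r.sensitivity == r.specificity == r.precision == r.f1 == 1.0

    def test_f1_fixed_point_when_pr_equals_re(self):
        # symmetric errors: precision == recall == 2/3 == F1
        cm = np.array([[4, 2], [2, 4]])
        r = mx.binary_rates(cm, 0)
        assert r.precision == pytest.approx(r.recall)
        assert r.f1 == pytest.approx(r.precision)

    def test_zero_denominator_flagged_not_crashed(self):
        cm = np.array([[0, 0], [0, 9]])  # class 0 absent
        r = mx.binary_rates(cm, 0)
        assert r.sensitivity == 0.0 and r.precision == 0.0
        assert r.degenerate

    def test_empty_matrix_rejected(self):
        with pytest.raises(mx.EmptyEvaluationError):
            mx.binary_rates(np.zeros((2, 2), dtype=int), 0)


class TestCohenKappa:
    def test_perfect_agreement(self):
        r = mx.cohen_kappa([0, 1, 2, 3, 4], [0, 1, 2, 3, 4])
        assert r.kappa == 1.0 and r.po == 1.0

    def test_hand_marginal_case(self):
        r = mx.cohen_kappa([0, 0, 1, 1], [0, 1, 0, 1])
        assert r.po == pytest.approx(0.5)
        assert r.pe == pytest.approx(0.5)
        assert r.kappa == pytest.approx(0.0)

    def test_contingency_arithmetic(self):
        # confusion [[2,1],[1,2]]: Po=4/6, Pe=1/2, kappa=1/3
        y_true = [0, 0, 0, 1, 1, 1]
        y_pred = [0, 0, 1, 0, 1, 1]
        r = mx.cohen_kappa(y_true, y_pred)
        assert r.po == pytest.approx(4 / 6)
        assert r.pe == pytest.approx(0.5)
        assert r.kappa == pytest.approx(1 / 3)

    def test_degenerate_single_class_marginals(self):
        r = mx.cohen_kappa([0, 0, 0], [0, 0, 0])
        assert r.kappa == 1.0 and r.degenerate

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(3)
        for _ in range(20):
            y_true = rng.integers(0, 4, 60)
            y_pred = rng.integers(0, 4, 60)
            assert mx.cohen_kappa(y_true, y_pred).kappa == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-12
            )


class TestRocAuc:
    def test_perfectly_ordered_scores(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        macro, per_class, _ = mx.roc_auc_ovr(y, scores)
        assert macro == 1.0 and per_class == {0: 1.0, 1: 1.0}

    def test_anti_ordered_scores(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([[0.1, 0.9], [0.2, 0.8], [0.9, 0.1], [0.8, 0.2]])
        macro, _, _ = mx.roc_auc_ovr(y, scores)
        assert macro == 0.0

    def test_all_ties_give_half(self):
        y = np.array([0, 1, 0, 1])
        macro, per_class, _ = mx.roc_auc_ovr(y, np.ones((4, 2)))
        assert macro == 0.5 and all(v == 0.5 for v in per_class.values())

    def test_absent_class_skipped_with_flag(self):
        y = np.array([0, 0, 1, 1])
        scores = np.random.default_rng(0).random((4, 3))
        _, per_class, skipped = mx.roc_auc_ovr(y, scores)
        assert skipped == [2]
        assert set(per_class) == {0, 1}

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        y = rng.integers(0, 3, 80)
        scores = rng.standard_normal((80, 3))
        macro, per_class, _ = mx.roc_auc_ovr(y, scores)
        for c in range(3):
            expected = roc_auc_score((y == c).astype(int), scores[:, c])
            assert per_class[c] == pytest.approx(expected, abs=1e-12)


class TestMulticlassReport:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 3, 4] * 4)
        report = mx.multiclass_report(y, y)
        assert report.accuracy == 1.0
        assert report.kappa.kappa == 1.0
        assert report.macro_f1 == 1.0
        assert report.macro_sensitivity == 1.0

    def test_uniform_random_predictions_near_chance(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 5, 10_000)
        y_pred = rng.integers(0, 5, 10_000)
        report = mx.multiclass_report(y_true, y_pred)
        assert report.accuracy == pytest.approx(0.2, abs=0.02)
        assert report.kappa.kappa == pytest.approx(0.0, abs=0.03)

    def test_macro_f1_invariant_under_relabeling(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 4, 300)
        y_pred = rng.integers(0, 4, 300)
        perm = np.array([2, 3, 1, 0])
        r1 = mx.multiclass_report(y_true, y_pred)
        r2 = mx.multiclass_report(perm[y_true], perm[y_pred])
        assert r1.macro_f1 == pytest.approx(r2.macro_f1, abs=1e-12)

    def test_accuracy_equals_micro_recall(self):
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 5, 400)
        y_pred = rng.integers(0, 5, 400)
        report = mx.multiclass_report(y_true, y_pred)
        assert report.accuracy == pytest.approx(report.micro_f1, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rates_bounded_on_fuzzed_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        k = int(rng.integers(2, 6))
        y_true = rng.integers(0, k, n)
        y_pred = rng.integers(0, k, n)
        report = mx.multiclass_report(y_true, y_pred, n_classes=k)
        for value in (
            report.accuracy, report.macro_sensitivity, report.macro_specificity,
            report.macro_precision, report.macro_f1,
        ):
            assert 0.0 <= value <= 1.0
        assert -1.0 <= report.kappa.kappa <= 1.0

    def test_json_serializable(self):
        import json

        y = np.array([0, 1, 1, 0])
        scores = np.random.default_rng(0).random((4, 2))
        report = mx.multiclass_report(y, y, scores)
        parsed = json.loads(report.to_json())
        assert parsed["accuracy"] == 1.0
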