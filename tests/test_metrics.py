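import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from loopanchor.metrics import (
    ConfusionCounts,
    accuracy,
    auprc,
    auroc,
    confusion,
    evaluate,
    f1,
    mcc,
    precision,
    sensitivity,
    specificity,
)


def random_counts(rng, allow_degenerate=False):
    while True:
        cc = ConfusionCounts(*(int(v) for v in rng.integers(0, 40, 4)))
        if allow_degenerate or min(cc.tp + cc.fn, cc.tn + cc.fp,
                                   cc.tp + cc.fp, cc.tn + cc.fn) > 0:
            return cc


class TestConfusion:
    def test_simple_tally(self):
        cc = confusion([1, 0], [0.9, 0.1])
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (1, 1, 0, 0)

    def test_threshold_is_inclusive(self):
        cc = confusion([1, 0, 1], [0.5, 0.5, 0.5])
        assert cc.tp == 2 and cc.fp == 1 and cc.tn == 0 and cc.fn == 0

    def test_random_pairs_match_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 50)
        scores = rng.random(50)
        cc = confusion(labels, scores, 0.4)
        tp = fp = tn = fn = 0
        for y, s in zip(labels, scores):
            p = s >= 0.4
            tp += p and y; fp += p and not y
            tn += (not p) and not y; fn += (not p) and y
        assert (cc.tp, cc.fp, cc.tn, cc.fn) == (tp, fp, tn, fn)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [0.5])


class TestFormulaMetrics:
    def test_sensitivity_example(self):
        assert sensitivity(ConfusionCounts(8, 0, 0, 2)) == 0.8

    def test_degenerate_precision_is_zero(self):
        assert precision(ConfusionCounts(0, 0, 10, 5)) == 0.0

    def test_random_counts_match_independent_formulas(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            cc = random_counts(rng)
            tp, fp, tn, fn = cc.tp, cc.fp, cc.tn, cc.fn
            assert sensitivity(cc) == pytest.approx(tp / (tp + fn))
            assert specificity(cc) == pytest.approx(tn / (tn + fp))
            assert precision(cc) == pytest.approx(tp / (tp + fp))
            assert accuracy(cc) == pytest.approx((tp + tn) / (tp + fp + tn + fn))
            p, r = tp / (tp + fp), tp / (tp + fn)
            expected_f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            assert f1(cc) == pytest.approx(expected_f1)


class TestMcc:
    def test_perfect_prediction(self):
        assert mcc(ConfusionCounts(50, 0, 50, 0)) == 1.0

    def test_total_misclassification(self):
        assert mcc(ConfusionCounts(0, 50, 0, 50)) == -1.0

    def test_degenerate_is_zero(self):
        assert mcc(ConfusionCounts(10, 0, 0, 0)) == 0.0

    def test_random_counts_match_high_precision_evaluation(self):
        from fractions import Fraction
        rng = np.random.default_rng(2)
        for _ in range(100):
            cc = random_counts(rng)
            tp, fp, tn, fn = (Fraction(v) for v in (cc.tp, cc.fp, cc.tn, cc.fn))
            num = tp * tn - fp * fn
            den2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            expected = float(num) / float(den2) ** 0.5
            assert mcc(cc) == pytest.approx(expected, abs=1e-12)
            assert -1.0 <= mcc(cc) <= 1.0


def mann_whitney_auc(labels, scores):
    """Concordant-pair count (+ half ties) over all pos/neg pairs."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


class TestCurveMetrics:
    def test_perfect_separation(self):
        assert auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert auprc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_equal_scores(self):
        assert auroc([0, 1, 0, 1], [0.3, 0.3, 0.3, 0.3]) == 0.5

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(30), 2)  # rounding forces some ties
            assert auroc(labels, scores) == pytest.approx(
                mann_whitney_auc(labels, scores)
            )

    def test_cross_check_against_sklearn_trapezoid(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        scores = rng.random(200)
        assert auroc(labels, scores) == pytest.approx(
            roc_auc_score(labels, scores)
        )
        assert auprc(labels, scores) == pytest.approx(
            average_precision_score(labels, scores)
        )

    def test_auprc_matches_stepwise_oracle_without_ties(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        scores = rng.permutation(np.linspace(0.01, 0.99, 40))  # tie-free
        order = np.argsort(scores)[::-1]
        sorted_labels = labels[order]
        tp = 0
        ap = 0.0
        for k, y in enumerate(sorted_labels, start=1):
            if y == 1:
                tp += 1
                ap += tp / k
        assert auprc(labels, scores) == pytest.approx(ap / sorted_labels.sum())

    def test_score_negation_complements_auroc(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.permutation(np.arange(50)).astype(float)  # no ties
        assert auroc(labels, scores) + auroc(labels, -scores) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 1, 1], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            auprc([0, 0], [0.1, 0.2])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = rng.random(60)
        perm = rng.permutation(60)
        base = evaluate(labels, scores)
        permuted = evaluate(labels[perm], scores[perm])
        assert base == permuted
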