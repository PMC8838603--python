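import math

import numpy as np
import pytest

from rxnsa.curation import ES, HS
from rxnsa.metrics import accuracy, evaluate, mcc, roc_auc


def trapezoid_auc(scores, positives):
    """Oracle: explicit threshold sweep + trapezoid integration."""
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    thresholds = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    n_pos, n_neg = positives.sum(), (~positives).sum()
    for t in thresholds:
        predicted = scores >= t
        tpr.append(np.sum(predicted & positives) / n_pos)
        fpr.append(np.sum(predicted & ~positives) / n_neg)
    return float(np.trapezoid(tpr, fpr))


def _scores_labels(tp, tn, fp, fn):
    scores = [1.0] * tp + [0.0] * fn + [1.0] * fp + [0.0] * tn
    labels = [ES] * (tp + fn) + [HS] * (fp + tn)
    return scores, labels


class TestWorkedCases:
    def test_confusion_40_30_10_20(self):
        report = evaluate(*_scores_labels(40, 30, 10, 20))
        assert report.confusion == (40, 30, 10, 20)
        assert report.acc == pytest.approx(0.7)
        assert report.mcc == pytest.approx(1000 / math.sqrt(6_000_000))
        assert report.mcc == pytest.approx(0.4082, abs=5e-5)

    def test_perfect_classifier(self):
        report = evaluate([1.0, 1.0, 0.0], [ES, ES, HS])
        assert (report.acc, report.mcc, report.auc) == (1.0, 1.0, 1.0)

    def test_inverted_classifier(self):
        report = evaluate([0.0, 0.0, 1.0], [ES, ES, HS])
        assert report.mcc == -1.0 and report.auc == 0.0

    def test_zero_denominator_mcc_is_zero(self):
        # all predicted positive: TN = FN = 0
        report = evaluate([1.0, 1.0], [ES, HS])
        assert report.mcc == 0.0

    def test_single_class_gives_no_auc_but_mcc_zero(self):
        report = evaluate([0.9, 0.1], [ES, ES])
        assert report.auc is None and report.mcc == 0.0


class TestFuzz:
    def test_formulas_match_direct_substitution(self):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            tp, tn, fp, fn = rng.integers(0, 30, size=4)
            if tp + tn + fp + fn == 0:
                continue
            acc = accuracy(tp, tn, fp, fn)
            m = mcc(tp, tn, fp, fn)
            assert acc == (tp + tn) / (tp + tn + fp + fn)
            denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
            expected = 0.0 if denom == 0 else \
                (tp * tn - fn * fp) / math.sqrt(denom)
            assert m == pytest.approx(expected)
            assert -1.0 <= m <= 1.0 and 0.0 <= acc <= 1.0

    def test_mcc_agrees_with_sklearn(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(1)
        for _ in range(200):
            y_true = rng.integers(0, 2, size=50)
            y_pred = rng.integers(0, 2, size=50)
            tp = int(np.sum((y_true == 1) & (y_pred == 1)))
            tn = int(np.sum((y_true == 0) & (y_pred == 0)))
            fp = int(np.sum((y_true == 0) & (y_pred == 1)))
            fn = int(np.sum((y_true == 1) & (y_pred == 0)))
            assert mcc(tp, tn, fp, fn) == \
                pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)


class TestAuc:
    @pytest.mark.parametrize("n,tie_fraction", [(10, 0.0), (50, 0.3),
                                                (200, 0.6), (7, 1.0)])
    def test_rank_statistic_equals_trapezoid_oracle(self, n, tie_fraction):
        rng = np.random.default_rng(n)
        scores = rng.random(n)
        ties = rng.random(n) < tie_fraction
        scores[ties] = np.round(scores[ties], 1)  # force tied values
        positives = rng.random(n) < 0.5
        if positives.all() or not positives.any():
            positives[0] = True
            positives[-1] = False
        assert roc_auc(scores, positives) == \
            pytest.approx(trapezoid_auc(scores, positives), abs=1e-12)

    def test_invariant_to_joint_permutation(self):
        rng = np.random.default_rng(3)
        scores = rng.random(80)
        labels = [ES if x else HS for x in rng.random(80) < 0.5]
        base = evaluate(scores, labels)
        perm = rng.permutation(80)
        shuffled = evaluate(scores[perm], [labels[i] for i in perm])
        assert shuffled.auc == pytest.approx(base.auc)
        assert shuffled.confusion == base.confusion

    def test_label_independent_scores_give_mcc_near_zero(self):
        rng = np.random.default_rng(4)
        n = 4000
        scores = rng.random(n)
        labels = [ES] * (n // 2) + [HS] * (n // 2)
        report = evaluate(scores, labels)
        assert abs(report.mcc) <= 0.05

    def test_empty_or_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])
        with pytest.raises(ValueError):
            evaluate([0.5], [ES, HS])
        with pytest.raises(ValueError):
            evaluate([0.5], ["yes"])


class TestPropertyBased:
    """Invariants under hypothesis-generated inputs (derandomized)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.integers(0, 100), min_size=4, max_size=4))
    @settings(max_examples=300, derandomize=True)
    def test_mcc_bounded_and_symmetric_under_class_swap(self, cm):
        tp, tn, fp, fn = cm
        value = mcc(tp, tn, fp, fn)
        assert -1.0 <= value <= 1.0
        # swapping the positive class swaps TP<->TN and FP<->FN: MCC invariant
        assert mcc(tn, tp, fn, fp) == pytest.approx(value)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=60),
           st.data())
    @settings(max_examples=200, derandomize=True)
    def test_auc_of_complemented_scores_is_one_minus_auc(self, scores, data):
        positives = data.draw(self.st.lists(
            self.st.booleans(), min_size=len(scores), max_size=len(scores)))
        positives = np.array(positives)
        if positives.all() or not positives.any():
            positives[0] = True
            positives[-1] = False
        # round so that 1 - s preserves the score ordering exactly
        scores = np.round(np.array(scores), 3)
        assert roc_auc(1.0 - scores, positives) == \
            pytest.approx(1.0 - roc_auc(scores, positives))
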