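import numpy as np
import pytest

from lstaloc.metrics import (
    accuracy,
    compute_report,
    confusion_counts,
    macro_auc,
    macro_f1,
    macro_mcc,
    macro_precision_recall,
    micro_auc,
    micro_auprc,
)

# -- independent oracles ------------------------------------------------------


def auroc_pair_counting(scores, labels):
    """Mann-Whitney: concordant pairs + half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def auprc_stepwise(scores, labels):
    """Step-wise PR area: sum of (recall step) * precision at each threshold
    group of tied scores, walking thresholds from high to low."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    P = y.sum()
    tp = fp = 0
    area = 0.0
    i = 0
    prev_tp = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tp += y[i:j].sum()
        fp += (j - i) - y[i:j].sum()
        precision = tp / (tp + fp)
        area += (tp - prev_tp) / P * precision
        prev_tp = tp
        i = j
    return area


def one_vs_rest(y, n):
    out = np.zeros((len(y), n), dtype=int)
    out[np.arange(len(y)), y] = 1
    return out


# -- pinned examples ----------------------------------------------------------


def test_confusion_counts_hand_example():
    counts = confusion_counts([0, 0, 1, 1], [0, 1, 1, 1], 2)
    tp, fp, fn, tn = counts[0]
    assert (tp, fp, fn) == (1, 0, 1)
    tp, fp, fn, tn = counts[1]
    assert (tp, fp, fn) == (2, 1, 0)
    # TP + FN equals class support
    np.testing.assert_array_equal(counts[:, 0] + counts[:, 2], [2, 2])


def test_macro_f1_hand_example():
    counts = confusion_counts([0, 0, 1, 1], [0, 1, 1, 1], 2)
    assert macro_f1(counts) == pytest.approx((2 / 3 + 0.8) / 2, abs=1e-4)


def test_perfect_and_inverted_predictions():
    y = np.array([0, 1, 0, 1])
    perfect = confusion_counts(y, y, 2)
    assert macro_f1(perfect) == 1.0
    assert macro_mcc(perfect) == 1.0
    inverted = confusion_counts(y, 1 - y, 2)
    assert macro_f1(inverted) == 0.0
    assert macro_mcc(inverted) == -1.0


def test_mcc_zero_numerator_and_degenerate_denominator():
    counts = np.array([[1, 1, 1, 1]])  # TP=TN=FP=FN=1 -> numerator 0
    assert macro_mcc(counts) == 0.0
    counts = np.array([[0, 0, 2, 2]])  # TP+FP = 0 -> 0 substituted
    assert macro_mcc(counts) == 0.0


def test_binary_auroc_hand_example():
    scores = np.array([0.9, 0.8, 0.4, 0.3])
    labels = np.array([1, 0, 1, 0])
    # 3 of 4 positive-negative pairs concordant
    two_col = np.stack([1 - scores, scores], axis=1)
    assert macro_auc(two_col, labels) == pytest.approx(0.75)
    assert auroc_pair_counting(scores, labels) == pytest.approx(0.75)


def test_tied_scores_give_half_credit():
    scores = np.full((6, 2), 0.5)
    labels = np.array([0, 1, 0, 1, 0, 1])
    assert micro_auc(scores, labels) == pytest.approx(0.5)
    assert macro_auc(scores, labels) == pytest.approx(0.5)


def test_perfect_separation():
    labels = np.array([1, 1, 0, 0])
    scores = np.stack([[0.1, 0.2, 0.9, 0.8], [0.9, 0.8, 0.1, 0.2]], axis=1)
    y = 1 - labels  # class-1 column high for label 1
    assert micro_auc(scores, labels) == pytest.approx(1.0)
    assert micro_auprc(scores, labels) == pytest.approx(1.0)


def test_accuracy_is_mean_correctness(rng):
    y = rng.integers(0, 4, 50)
    p = rng.integers(0, 4, 50)
    assert accuracy(y, p) == np.mean(y == p)


def test_errors_on_degenerate_inputs():
    with pytest.raises(ValueError):
        confusion_counts([], [], 3)
    with pytest.raises(ValueError):
        micro_auc(np.zeros((0, 2)), np.zeros(0, dtype=int))


# -- oracle equivalence sweep -------------------------------------------------


def test_metrics_match_brute_force_oracles(rng):
    """50 random instances; deviation < 1e-9 against pair-counting AUROC and
    direct step-wise PR summation."""
    for _ in range(50):
        m = int(rng.integers(8, 30))
        n = int(rng.integers(2, 5))
        y = rng.integers(0, n, m)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, n, m)
        scores = rng.random((m, n))
        if rng.random() < 0.3:  # exercise tie handling
            scores = np.round(scores, 1)
        t = one_vs_rest(y, n)
        flat_s, flat_t = scores.ravel(), t.ravel()
        assert micro_auc(scores, y) == pytest.approx(
            auroc_pair_counting(flat_s, flat_t), abs=1e-9
        )
        assert micro_auprc(scores, y) == pytest.approx(
            auprc_stepwise(flat_s, flat_t), abs=1e-9
        )
        per_class = [
            auroc_pair_counting(scores[:, c], t[:, c])
            for c in range(n)
            if 0 < t[:, c].sum() < m
        ]
        assert macro_auc(scores, y) == pytest.approx(np.mean(per_class), abs=1e-9)


def test_report_bundles_all_metrics(rng):
    y = rng.integers(0, 3, 40)
    scores = rng.random((40, 3))
    scores[np.arange(40), y] += 0.7  # informative scores
    preds = scores.argmax(axis=1)
    report = compute_report(scores, y, preds)
    d = report.to_dict()
    assert set(d) == {
        "acc", "macro_precision", "macro_recall", "macro_f1", "macro_mcc",
        "mi_auc", "ma_auc", "mi_auprc", "per_class_counts",
    }
    assert 0 <= d["acc"] <= 1 and -1 <= d["macro_mcc"] <= 1
    assert d["mi_auc"] > 0.5  # informative by construction
    prec, rec = macro_precision_recall(confusion_counts(y, preds, 3))
    assert d["macro_precision"] == pytest.approx(prec)
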