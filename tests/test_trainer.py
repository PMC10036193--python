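"""Multitask loss weighting and the evaluation metrics."""
import numpy as np
import pytest

from vertemtl.nn import Tensor
from vertemtl.trainer import (LOSS_TERMS, LossWeights, classification_metrics,
                              confusion_matrix, multitask_loss, overlap_metrics,
                              roc_auc)


def _terms(values):
    return {name: Tensor(np.float32(v)) for name, v in zip(LOSS_TERMS, values)}


class TestMultitaskLoss:
    def test_all_zero_losses_and_weights_give_zero(self):
        total, bk = multitask_loss(_terms([0.0] * 6), LossWeights())
        assert float(total.data) == pytest.approx(0.0)
        assert set(bk) == set(LOSS_TERMS)

    def test_masking_removes_exactly_one_term(self):
        lw = LossWeights()
        vals = [0.5, 0.25, 1.0, 0.75, 0.1, 0.9]
        full, _ = multitask_loss(_terms(vals), lw)
        masked_terms = _terms(vals)
        masked_terms["dice"] = None
        masked, _ = multitask_loss(masked_terms, lw)
        # s_dice = 0: removing the term removes exp(0)*0.75 + 0
        assert float(full.data) - float(masked.data) == pytest.approx(0.75, abs=1e-6)

    def test_gradient_wrt_log_variance(self, rng):
        lw = LossWeights()
        for name, s0 in zip(LOSS_TERMS, rng.normal(scale=0.5, size=6)):
            lw.s[name].data = np.float32(s0)
        vals = rng.random(6).astype(np.float64)
        total, _ = multitask_loss(_terms(vals), lw)
        total.backward()
        for name, li in zip(LOSS_TERMS, vals):
            s = float(lw.s[name].data)
            expected = -np.exp(-s) * li + 1.0
            assert float(lw.s[name].grad) == pytest.approx(expected, abs=1e-4)

    def test_non_finite_term_names_culprit(self):
        terms = _terms([0.1] * 6)
        terms["boundary"] = Tensor(np.float32(np.nan))
        with pytest.raises(FloatingPointError, match="boundary"):
            multitask_loss(terms, LossWeights())

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            multitask_loss({n: None for n in LOSS_TERMS}, LossWeights())

    def test_clamp_bounds_effective_weights(self):
        lw = LossWeights()
        lw.s["cls"].data = np.float32(40.0)
        lw.s["dice"].data = np.float32(-40.0)
        lw.clamp(-2.0, 5.0)
        assert lw.effective_weight("cls") >= 1e-4  # never collapses
        assert lw.effective_weight("dice") <= np.exp(2.0) + 1e-6


class TestClassificationMetrics:
    def test_hand_arithmetic_example(self):
        # one-vs-rest counts TP=8 FP=2 FN=2 TN=88
        cm = np.array([[8, 1, 1],
                       [1, 44, 0],
                       [1, 0, 44]])
        rep = classification_metrics(cm)
        m = rep.per_class["normal"]
        assert m["accuracy"] == pytest.approx(0.96)
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["specificity"] == pytest.approx(88 / 90)
        assert m["f1"] == pytest.approx(0.8)

    def test_perfect_confusion(self):
        rep = classification_metrics(np.diag([5, 7, 9]))
        assert rep.overall_accuracy == 1.0
        for m in rep.per_class.values():
            assert m["accuracy"] == m["sensitivity"] == m["specificity"] == 1.0

    def test_undefined_rates_are_none_not_zero(self):
        cm = np.array([[0, 0, 0],
                       [0, 5, 0],
                       [0, 0, 5]])  # no "normal" truth or predictions
        m = classification_metrics(cm).per_class["normal"]
        assert m["sensitivity"] is None
        assert m["f1"] is None

    def test_overall_equals_support_weighted_recall(self, rng):
        for _ in range(10):
            cm = rng.integers(0, 20, size=(3, 3))
            cm += np.diag([1, 1, 1])  # ensure nonzero supports
            rep = classification_metrics(cm)
            recalls = [rep.per_class[n]["sensitivity"]
                       for n in ("normal", "osteopenia", "osteoporosis")]
            supports = cm.sum(axis=1)
            weighted = np.average(recalls, weights=supports)
            assert rep.overall_accuracy == pytest.approx(weighted)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(np.array([[1, -1, 0], [0, 1, 0], [0, 0, 1]]))

    def test_confusion_row_sums_are_supports(self, rng):
        y_true = rng.integers(0, 3, size=60)
        y_pred = rng.integers(0, 3, size=60)
        cm = confusion_matrix(y_true, y_pred)
        assert np.array_equal(cm.sum(axis=1), np.bincount(y_true, minlength=3))


def test_overlap_dice_iou_identity(rng):
    for _ in range(30):
        tp, fp, fn = rng.integers(1, 50, size=3)
        iou, dice = overlap_metrics(tp, fp, fn)
        assert dice == pytest.approx(2 * iou / (1 + iou), abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        truths = np.array([0, 0, 1, 1, 2, 2])
        scores = np.eye(3)[truths] * 10.0
        aucs = roc_auc(scores, truths)
        assert all(v == pytest.approx(1.0) for v in aucs.values())

    def test_random_scores_near_half(self, rng):
        n = 4000
        truths = rng.integers(0, 3, size=n)
        scores = rng.random((n, 3))
        aucs = roc_auc(scores, truths)
        for v in aucs.values():
            assert abs(v - 0.5) < 0.05

    def test_matches_mann_whitney_oracle(self, rng):
        truths = rng.integers(0, 3, size=200)
        scores = rng.random((200, 3))
        aucs = roc_auc(scores, truths)
        for k, name in enumerate(("normal", "osteopenia", "osteoporosis")):
            pos = scores[truths == k, k]
            neg = scores[truths != k, k]
            # U / (n+ * n-): the probability a positive outranks a negative
            u = sum((p > neg).sum() + 0.5 * (p == neg).sum() for p in pos)
            assert aucs[name] == pytest.approx(u / (len(pos) * len(neg)), abs=1e-9)

    def test_single_class_truth_signalled(self):
        with pytest.raises(ValueError):
            roc_auc(np.random.rand(5, 3), np.zeros(5, dtype=int))
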