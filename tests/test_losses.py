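"""Loss terms: hand-computed values, closed forms, masking conventions."""

import autograd.numpy as anp
import numpy as np
import pytest
from autograd import grad

from nucself.losses import (LossWeights, binary_loss, contrastive_loss,
                            distance_loss, mine_hard_negatives, prompt_loss,
                            total_loss)
from nucself.pseudolabel import BG, FG, IGNORE, PseudoLabel

from oracles import brute_contrastive


def _plabel(label, assign):
    return PseudoLabel(label=np.asarray(label, dtype=np.int8),
                       instance_assign=np.asarray(assign, dtype=np.int32))


class TestMaskedSegmentationLosses:
    def test_perfect_prediction_scores_zero(self):
        target = np.array([[1, 0], [0, 1]], dtype=np.int8)
        S = _plabel(target, target)
        pred = target.astype(np.float64)[None]
        # instance 1 owns all fg pixels
        S2 = _plabel(target, np.where(target == 1, 1, 0))
        assert prompt_loss(pred, S2) == pytest.approx(0.0, abs=1e-5)
        assert binary_loss(pred[0], S2.label) == pytest.approx(0.0, abs=1e-5)

    def test_all_ignored_pixels_give_zero_loss(self):
        S = _plabel(np.full((2, 2), IGNORE), np.zeros((2, 2)))
        assert prompt_loss(np.random.rand(1, 2, 2), S) == 0.0
        assert binary_loss(np.random.rand(2, 2), S.label) == 0.0

    def test_hand_computed_two_by_two_case(self):
        """Target [[1,0],[0,ignore]], prediction [[.9,.1],[.1,.5]]: BCE over
        the 3 valid pixels is -ln 0.9; soft-IoU loss is 1 - 0.9/1.2."""
        label = np.array([[FG, BG], [BG, IGNORE]], dtype=np.int8)
        assign = np.array([[1, 0], [0, 0]], dtype=np.int32)
        S = _plabel(label, assign)
        pred = np.array([[[0.9, 0.1], [0.1, 0.5]]])
        expected = -np.log(0.9) + (1 - 0.9 / (1.1 + 1.0 - 0.9))
        assert prompt_loss(pred, S) == pytest.approx(expected, abs=1e-6)
        assert binary_loss(pred[0], S.label) == pytest.approx(expected, abs=1e-6)

    def test_distance_loss_constant_offset(self):
        D = np.zeros((2, 4, 4))
        target = D + 0.2
        valid = np.ones((4, 4), dtype=bool)
        assert distance_loss(D, target, valid) == pytest.approx(0.2)
        assert distance_loss(target, target, valid) == 0.0
        assert distance_loss(D, target, np.zeros((4, 4), dtype=bool)) == 0.0

    def test_distance_loss_matches_bruteforce_mean(self, rng):
        D = rng.standard_normal((2, 6, 6))
        T = rng.standard_normal((2, 6, 6))
        valid = rng.random((6, 6)) > 0.4
        ref = np.abs(D - T)[:, valid].mean()
        assert distance_loss(D, T, valid) == pytest.approx(ref, rel=1e-6)

    def test_losses_nonnegative_and_finite(self, rng):
        for _ in range(10):
            pred = rng.random((2, 8, 8))
            label = rng.integers(-1, 2, size=(8, 8)).astype(np.int8)
            assign = np.where(label == 1, rng.integers(1, 3, size=(8, 8)), 0)
            S = _plabel(label, assign)
            for v in (prompt_loss(pred, S), binary_loss(pred[0], S.label)):
                assert np.isfinite(v) and v >= 0


class TestHardNegativeMining:
    def test_no_candidates_below_threshold(self, rng):
        B = np.full((8, 8), 0.69)
        label = np.zeros((8, 8), dtype=np.int8)
        assert len(mine_hard_negatives(B, label, rng)) == 0

    def test_few_candidates_all_returned(self, rng):
        B = np.zeros((8, 8))
        B[0, :5] = 0.9
        label = np.zeros((8, 8), dtype=np.int8)
        coords = mine_hard_negatives(B, label, rng)
        assert len(coords) == 5
        assert all(B[r, c] > 0.7 and label[r, c] == BG for r, c in coords)

    def test_many_candidates_capped_at_hundred(self, rng):
        B = np.full((32, 32), 0.95)
        label = np.zeros((32, 32), dtype=np.int8)
        label[:8] = FG  # foreground rows are not eligible
        label[:8][label[:8] == FG] = FG
        assign = np.where(label == FG, 1, 0)
        coords = mine_hard_negatives(B, label, rng)
        assert len(coords) == 100
        assert all(label[r, c] == BG and B[r, c] > 0.7 for r, c in coords)

    def test_deterministic_under_fixed_rng(self):
        B = np.random.default_rng(0).random((32, 32))
        label = np.zeros((32, 32), dtype=np.int8)
        a = mine_hard_negatives(B, label, np.random.default_rng(5))
        b = mine_hard_negatives(B, label, np.random.default_rng(5))
        assert np.array_equal(a, b)


def _unit(v):
    v = np.asarray(v, dtype=np.float64)
    return v / np.linalg.norm(v)


class TestContrastiveLoss:
    def test_zero_negatives_gives_exactly_zero(self, rng):
        anchors = np.stack([_unit(rng.standard_normal(8)) for _ in range(3)])
        proto = _unit(rng.standard_normal(8))
        assert float(contrastive_loss(anchors, proto, None)) == 0.0
        assert float(contrastive_loss(anchors, proto, np.zeros((0, 8)))) == 0.0

    def test_aligned_anchor_orthogonal_tiny_loss(self):
        """sim(q, z+) = 1, one negative at sim = -1, tau = 0.1: the softmax
        ratio is within 2e-9 of 1."""
        q = np.array([[1.0, 0.0]])
        proto = np.array([1.0, 0.0])
        neg = np.array([[-1.0, 0.0]])
        val = float(contrastive_loss(q, proto, neg, tau=0.1))
        assert val == pytest.approx(np.log1p(np.exp(-20.0)), abs=1e-12)
        assert val < 1e-8

    def test_symmetric_zero_similarity_gives_ln2(self):
        q = np.array([[1.0, 0.0]])
        proto = np.array([0.0, 1.0])
        neg = np.array([[0.0, -1.0]])
        assert float(contrastive_loss(q, proto, neg, tau=0.1)) == pytest.approx(
            np.log(2.0), abs=1e-9)

    def test_matches_bruteforce_formula(self, rng):
        anchors = np.stack([_unit(rng.standard_normal(16)) for _ in range(4)])
        proto = _unit(rng.standard_normal(16))
        negs = np.stack([_unit(rng.standard_normal(16)) for _ in range(7)])
        ref = brute_contrastive(anchors, proto, negs, 0.1)
        assert float(contrastive_loss(anchors, proto, negs, 0.1)) == pytest.approx(
            ref, rel=1e-9)

    def test_loss_decreases_as_prototype_similarity_rises(self, rng):
        """With the anchor and negatives fixed, raising sim(q, z+) strictly
        lowers the loss."""
        negs = np.stack([_unit(rng.standard_normal(4)) for _ in range(5)])
        q = np.array([[1.0, 0, 0, 0]])
        losses = []
        for ang in np.linspace(np.pi / 2, 0, 8):
            proto = np.array([np.cos(ang), np.sin(ang), 0, 0])
            losses.append(float(contrastive_loss(q, proto, negs, 0.1)))
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_gradient_reaches_prototype(self, rng):
        anchors = np.stack([_unit(rng.standard_normal(8)) for _ in range(3)])
        negs = np.stack([_unit(rng.standard_normal(8)) for _ in range(4)])

        def f(proto):
            p = proto / anp.sqrt(anp.sum(proto * proto))
            return contrastive_loss(anchors, p, negs, 0.1)

        g = grad(f)(_unit(rng.standard_normal(8)))
        assert np.linalg.norm(g) > 0


class TestTotalLoss:
    def test_zero_components_zero_total(self):
        assert total_loss(0, 0, 0, 0) == 0

    def test_default_weights_sum(self):
        # lambda_P, lambda_B, lambda_D, lambda_C = 1, 1, 5, 1
        assert total_loss(1.0, 1.0, 1.0, 1.0) == pytest.approx(8.0)

    def test_contrastive_arm_can_be_disabled(self):
        w = LossWeights(lambda_C=0.0)
        assert total_loss(0, 0, 0, 123.0, w) == 0.0

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_D=-1)
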