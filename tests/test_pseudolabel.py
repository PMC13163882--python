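"""Pseudo-label refinement: closed forms, printed thresholds and the
brute-force per-pixel oracle."""

import numpy as np
import pytest

from nucself.pseudolabel import (EmaSchedule, alpha_at, assemble_instance_label,
                                 assemble_prompt_label, base_ignore_set,
                                 consensus_sets,
                                 dense_targets_from_instance_label, ema_blend,
                                 instance_ignore_mask, overlap_count,
                                 pixel_entropy, prompt_ignore_mask,
                                 static_baseline_labels, PseudoLabel, FG, BG,
                                 IGNORE)

from conftest import random_prob_stack
from oracles import brute_prompt_label, brute_refinement


class TestAlphaSchedule:
    @pytest.mark.parametrize("t,expected", [(0, 1.0), (50, 0.5), (100, 0.0)])
    def test_linear_endpoints_and_midpoint(self, t, expected):
        assert alpha_at(EmaSchedule("linear", T=100), t) == pytest.approx(expected)

    def test_constant_holds_everywhere(self):
        sched = EmaSchedule("constant", T=100, param=0.5)
        assert all(alpha_at(sched, t) == 0.5 for t in range(0, 101, 7))

    def test_stepwise_switches_at_split(self):
        sched = EmaSchedule("stepwise", T=100)
        assert alpha_at(sched, 49) == 1.0
        assert alpha_at(sched, 50) == 0.0

    def test_exponential_decays_within_unit_interval(self):
        sched = EmaSchedule("exponential", T=100, param=0.5)
        vals = [alpha_at(sched, t) for t in range(101)]
        assert vals[0] == 1.0
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("t", [-1, 101])
    def test_out_of_range_epoch_rejected(self, t):
        with pytest.raises(ValueError):
            alpha_at(EmaSchedule("linear", T=100), t)


class TestEmaBlend:
    def test_boundary_coefficients_select_each_stack(self, rng):
        a, b = rng.random((2, 3, 8, 8))
        assert np.array_equal(ema_blend(a, b, 1.0), a)
        assert np.array_equal(ema_blend(a, b, 0.0), b)

    def test_midpoint_arithmetic(self):
        a = np.full((1, 1, 1), 0.8)
        b = np.full((1, 1, 1), 0.4)
        assert ema_blend(a, b, 0.5)[0, 0, 0] == pytest.approx(0.6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ema_blend(np.zeros((2, 4, 4)), np.zeros((3, 4, 4)), 0.5)


class TestEntropyAndOverlap:
    @pytest.mark.parametrize("p,expected", [
        (0.0, 0.0), (1.0, 0.0),
        (0.5, np.log(2)),
        (0.95, 0.19852),  # below the 0.3 gate: confident pixels survive
    ])
    def test_binary_entropy_closed_form(self, p, expected):
        m = np.full((1, 1, 1), p)
        assert pixel_entropy(m)[0, 0] == pytest.approx(expected, abs=1e-4)

    def test_overlap_counts_instances_above_half(self):
        m = np.zeros((3, 2, 2))
        m[0, 0, 0] = m[1, 0, 0] = 0.9
        m[:, 1, 1] = 0.6
        F = overlap_count(m)
        assert F[0, 0] == 2 and F[1, 1] == 3 and F[0, 1] == 0

    def test_ignore_mask_thresholds_as_printed(self):
        H = np.array([[0.31, 0.0], [0.0, 0.0]])
        F = np.array([[0, 2], [1, 0]])
        M = prompt_ignore_mask(H, F)
        assert M[0, 0] and M[0, 1]          # H > 0.3; F >= 2
        assert not M[1, 0] and not M[1, 1]  # F == 1 alone is fine


class TestConsensusLogic:
    def test_printed_consensus_examples(self):
        m_u = np.array([[[0.9, 0.1]]])
        B = np.array([[0.8, 0.2]])
        F = overlap_count(m_u)
        A_fg, A_bg = consensus_sets(m_u, B, F)
        assert A_fg[0, 0] and not A_bg[0, 0]
        assert A_bg[0, 1] and not A_fg[0, 1]

    def test_branch_conflict_enters_base_ignore(self):
        m_u = np.array([[[0.9, 0.9]]])
        B = np.array([[0.9, 0.1]])
        I = base_ignore_set(m_u, B, np.zeros((1, 2)))
        assert not I[0, 0] and I[0, 1]

    def test_consensus_recovers_from_ignore(self):
        I_base = np.array([[True, False]])
        F = np.array([[1, 3]])
        A_fg = np.array([[True, False]])
        A_bg = np.zeros((1, 2), dtype=bool)
        M_I = instance_ignore_mask(I_base, F, A_fg, A_bg)
        assert not M_I[0, 0]  # recovered by foreground consensus
        assert M_I[0, 1]      # multi-instance pixel, no consensus

    def test_vectorized_logic_matches_per_pixel_oracle(self, rng):
        """Exact agreement with a brute-force per-pixel evaluator on random
        blob-like stacks (the core refinement-correctness check)."""
        for _ in range(25):
            m_u = random_prob_stack(rng)
            B = rng.random(m_u.shape[1:])
            ref = brute_refinement(m_u, B)
            H_map = pixel_entropy(m_u)
            F_map = overlap_count(m_u)
            A_fg, A_bg = consensus_sets(m_u, B, F_map)
            I_base = base_ignore_set(m_u, B, H_map)
            np.testing.assert_allclose(H_map, ref["H"], atol=1e-12)
            assert np.array_equal(F_map, ref["F"])
            assert np.array_equal(prompt_ignore_mask(H_map, F_map), ref["M_p"])
            assert np.array_equal(A_fg, ref["A_fg"])
            assert np.array_equal(A_bg, ref["A_bg"])
            assert np.array_equal(I_base, ref["I_base"])
            assert np.array_equal(
                instance_ignore_mask(I_base, F_map, A_fg, A_bg), ref["M_I"])

    def test_consensus_sets_always_disjoint(self, rng):
        for _ in range(20):
            m_u = random_prob_stack(rng)
            B = rng.random(m_u.shape[1:])
            A_fg, A_bg = consensus_sets(m_u, B, overlap_count(m_u))
            assert not np.any(A_fg & A_bg)

    def test_recovery_guarantee(self, rng):
        """(A_fg ∪ A_bg) never intersects the final ignore mask."""
        for _ in range(20):
            m_u = random_prob_stack(rng)
            B = rng.random(m_u.shape[1:])
            F = overlap_count(m_u)
            A_fg, A_bg = consensus_sets(m_u, B, F)
            I_base = base_ignore_set(m_u, B, pixel_entropy(m_u))
            M_I = instance_ignore_mask(I_base, F, A_fg, A_bg)
            assert not np.any((A_fg | A_bg) & M_I)

    def test_threshold_monotonicity(self, rng):
        """Lowering the entropy gate never shrinks M_p; raising the
        foreground-consensus gate never grows A_fg."""
        m_u = random_prob_stack(rng, K=3, shape=(24, 24))
        B = rng.random((24, 24))
        H_map = pixel_entropy(m_u)
        F_map = overlap_count(m_u)
        loose = prompt_ignore_mask(H_map, F_map, entropy_thresh=0.3)
        tight = prompt_ignore_mask(H_map, F_map, entropy_thresh=0.1)
        assert np.all(loose <= tight)
        mu_max = m_u.max(axis=0)
        a_07 = (mu_max > 0.5) & (B > 0.7) & (F_map < 2)
        a_09 = (mu_max > 0.5) & (B > 0.9) & (F_map < 2)
        assert np.all(a_09 <= a_07)


class TestLabelAssembly:
    def test_all_zero_probs_give_pure_background(self):
        m_u = np.zeros((2, 4, 4))
        S = assemble_prompt_label(m_u, np.zeros((4, 4), dtype=bool))
        assert np.all(S.label == BG)
        assert np.all(S.instance_assign == 0)

    def test_prompt_label_matches_per_pixel_oracle(self, rng):
        for _ in range(10):
            m_u = random_prob_stack(rng)
            H_map = pixel_entropy(m_u)
            F_map = overlap_count(m_u)
            M_p = prompt_ignore_mask(H_map, F_map)
            S = assemble_prompt_label(m_u, M_p)
            label, assign = brute_prompt_label(m_u, M_p)
            assert np.array_equal(S.label, label)
            assert np.array_equal(S.instance_assign, assign)

    def test_uncertain_boundary_ring_is_ignored(self):
        """A blob whose rim sits near 0.5 probability (entropy > 0.3) keeps
        a confident core and an ignored rim."""
        yy, xx = np.mgrid[0:21, 0:21]
        d = np.sqrt((yy - 10.0) ** 2 + (xx - 10.0) ** 2)
        m = 1.0 / (1.0 + np.exp(d - 6.0))
        m_u = m[None]
        M_p = prompt_ignore_mask(pixel_entropy(m_u), overlap_count(m_u))
        S = assemble_prompt_label(m_u, M_p)
        assert S.label[10, 10] == FG
        assert S.label[0, 0] == BG
        ring = (np.abs(d - 6.0) < 1.0)
        assert np.all(S.label[ring] == IGNORE)

    def test_instance_label_argmax_and_tie_rule(self):
        m_u = np.zeros((2, 1, 2))
        m_u[:, 0, 0] = [0.9, 0.6]
        m_u[:, 0, 1] = [0.8, 0.8]
        S = assemble_instance_label(m_u, np.ones((1, 2)) * 0.9,
                                    np.zeros((1, 2), dtype=bool))
        assert S.instance_assign[0, 0] == 1
        assert S.instance_assign[0, 1] == 1  # exact tie -> lowest index

    def test_full_ignore_mask_gives_all_ignore(self):
        m_u = np.full((1, 3, 3), 0.9)
        S = assemble_instance_label(m_u, np.ones((3, 3)), np.ones((3, 3), dtype=bool))
        assert np.all(S.label == IGNORE)


class TestDenseTargets:
    def _disc_label(self, r=7, size=21):
        yy, xx = np.mgrid[0:size, 0:size]
        inside = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= r ** 2
        label = np.where(inside, FG, BG).astype(np.int8)
        assign = np.where(inside, 1, 0).astype(np.int32)
        return PseudoLabel(label=label, instance_assign=assign)

    def test_offset_vanishes_at_centroid(self):
        d = dense_targets_from_instance_label(self._disc_label())
        assert d.D[0, 10, 10] == pytest.approx(0.0, abs=1e-6)
        assert d.D[1, 10, 10] == pytest.approx(0.0, abs=1e-6)

    def test_disc_offsets_point_toward_centroid(self):
        d = dense_targets_from_instance_label(self._disc_label())
        yy, xx = np.mgrid[0:21, 0:21]
        mask = (d.D[0] != 0) | (d.D[1] != 0)
        to_center = np.stack([10.0 - yy, 10.0 - xx])
        dot = (d.D[0] * to_center[0] + d.D[1] * to_center[1])[mask]
        assert np.all(dot > 0)

    def test_components_bounded_by_one(self, rng):
        m_u = random_prob_stack(rng, K=3, shape=(32, 32))
        S = assemble_instance_label(m_u, rng.random((32, 32)),
                                    np.zeros((32, 32), dtype=bool))
        d = dense_targets_from_instance_label(S)
        assert np.all(np.abs(d.D) <= 1.0)

    def test_all_ignore_label_has_empty_validity(self):
        label = np.full((5, 5), IGNORE, dtype=np.int8)
        S = PseudoLabel(label=label, instance_assign=np.zeros((5, 5), np.int32))
        d = dense_targets_from_instance_label(S)
        assert not d.valid.any()

    def test_offset_validity_covers_foreground_only(self):
        """The offset field is supervised on foreground pixels of instances
        large enough for a centroid; background and sub-3-px instances are
        excluded."""
        label = np.full((7, 7), BG, dtype=np.int8)
        assign = np.zeros((7, 7), np.int32)
        label[1:4, 1:4] = FG      # 9-px instance: valid
        assign[1:4, 1:4] = 1
        label[5, 5] = FG          # 1-px instance: too small
        assign[5, 5] = 2
        d = dense_targets_from_instance_label(PseudoLabel(label, assign))
        assert d.valid[2, 2]
        assert not d.valid[5, 5]
        assert not d.valid[0, 0]  # background carries no offset supervision


class TestStaticBaseline:
    def test_equals_alpha_one_prompt_label(self, rng):
        m_base = random_prob_stack(rng, K=3, shape=(16, 16))
        static = static_baseline_labels(m_base)
        m_u = ema_blend(m_base, rng.random(m_base.shape), 1.0)
        M_p = prompt_ignore_mask(pixel_entropy(m_u), overlap_count(m_u))
        fresh = assemble_prompt_label(m_u, M_p)
        assert np.array_equal(static.label, fresh.label)
        assert np.array_equal(static.instance_assign, fresh.instance_assign)
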