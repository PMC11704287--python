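import numpy as np
import pytest

from molprompt.autodiff import Tensor
from molprompt.chem_graph import BitFingerprint
from molprompt.losses import (
    ALIGNMENT_PRESETS,
    adaptive_margin_loss,
    alignment_regularization,
    alpha1,
    alpha2,
    attention_regularization,
    context_prediction_loss,
    overall_loss,
    scaffold_importance,
    triplet_loss,
    uniform_importance,
)


def fp(bits, n=512):
    return BitFingerprint(frozenset(bits), n, 2)


class TestMargins:
    def test_alpha1_examples(self):
        assert alpha1(fp({1, 2}), fp({1, 2})) == 0.0
        assert alpha1(fp({1, 2}), fp({3, 4}), offset=1.0) == 1.0
        assert alpha1(fp({1, 2, 3}), fp({2, 3, 4}), offset=1.0) == pytest.approx(0.5)

    def test_alpha1_bounds_and_offset_scaling(self):
        v = alpha1(fp({1}), fp({2}), offset=0.3)
        assert v == pytest.approx(0.3)
        with pytest.raises(ValueError):
            alpha1(fp({1}), fp({2}), offset=0.0)

    def test_alpha2_examples_and_antisymmetry(self):
        i, j, k = fp({1, 2}), fp({1, 2}), fp({9, 10})
        assert alpha2(i, j, j) == 0.0
        assert alpha2(i, j, k, offset=1.0) == pytest.approx(1.0)
        assert alpha2(i, j, k) == pytest.approx(-alpha2(i, k, j))


class TestAdaptiveMarginLoss:
    def test_zero_when_all_hinges_inactive(self):
        h_i = Tensor(np.zeros(8))
        h_pos = Tensor(np.zeros(8))
        h_j = Tensor(np.r_[2.0, np.zeros(7)])   # d(i,j)=2
        h_k = Tensor(np.r_[np.zeros(7), 5.0])   # d(i,k)=5
        val = adaptive_margin_loss(h_i, h_pos, h_j, h_k, 1.0, 1.0, 0.5)
        assert val.data == pytest.approx(0.0, abs=1e-6)

    def test_worked_hinge_value(self):
        # all representations coincident: every distance 0, loss = sum of margins
        z = Tensor(np.zeros(4))
        val = adaptive_margin_loss(z, z, z, z, 0.5, 0.25, 0.0)
        assert val.data == pytest.approx(0.75, abs=1e-5)

    def test_nonnegative_for_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vs = [Tensor(rng.normal(size=8)) for _ in range(4)]
            a1a, a1b, a2 = rng.uniform(0, 1, 3)
            assert adaptive_margin_loss(*vs, a1a, a1b, a2).data >= 0

    def test_reduces_to_fixed_margin_triplet_for_disjoint_fingerprints(self):
        # disjoint fingerprints: alpha1 = offset for both negatives; dropping
        # the alpha2 term leaves two conventional triplet losses
        rng = np.random.default_rng(1)
        offset = 1.0
        h_i, h_pos, h_j, h_k = (Tensor(rng.normal(size=16)) for _ in range(4))
        quad = adaptive_margin_loss(h_i, h_pos, h_j, h_k, offset, offset, 0.0)
        t_j = triplet_loss(h_i, h_pos, h_j, offset)
        t_k = triplet_loss(h_i, h_pos, h_k, offset)
        a2_term = max(
            0.0,
            np.linalg.norm(h_i.data - h_j.data) - np.linalg.norm(h_i.data - h_k.data),
        )
        assert quad.data == pytest.approx(t_j.data + t_k.data + a2_term, abs=1e-9)

    def test_scaling_embeddings_apart_drives_loss_to_zero(self):
        rng = np.random.default_rng(2)
        h_i = Tensor(rng.normal(size=8))
        h_pos = Tensor(h_i.data + 0.01 * rng.normal(size=8))
        h_j = Tensor(rng.normal(size=8))
        h_k = Tensor(rng.normal(size=8))
        scale = 100.0
        val = adaptive_margin_loss(
            h_i, h_pos, Tensor(h_j.data * scale), Tensor(h_k.data * scale * 10),
            1.0, 1.0, 0.5,
        )
        assert val.data == pytest.approx(0.0, abs=1e-9)


class TestContextPrediction:
    def test_perfect_motif_prediction_zeroes_smooth_l1(self):
        logits = Tensor(np.array([[10.0, -10.0, -10.0]]))
        target = np.array([0.2, 0.8])
        val = context_prediction_loss(logits, np.array([0]), Tensor(target), target)
        assert val.data == pytest.approx(0.0, abs=1e-6)

    def test_uniform_logits_give_log_c(self):
        C = 7
        logits = Tensor(np.zeros((4, C)))
        motif = Tensor(np.zeros(3))
        val = context_prediction_loss(logits, np.zeros(4, dtype=int), motif, np.zeros(3))
        assert val.data == pytest.approx(np.log(C))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            context_prediction_loss(Tensor(np.zeros((2, 3))), np.zeros(3, dtype=int),
                                    Tensor(np.zeros(3)), np.zeros(3))


class TestRegularization:
    def test_attention_equal_to_importance_is_zero(self):
        att = Tensor(np.array([0.25, 0.25, 0.25, 0.25]))
        assert attention_regularization(att, uniform_importance(4)).data == 0.0

    def test_uniform_importance_construction(self):
        assert uniform_importance(4).tolist() == [0.25] * 4

    def test_scaffold_importance_zero_off_scaffold(self):
        imp = scaffold_importance(np.array([1, 1, 0, 0, 1]))
        assert imp[2] == imp[3] == 0.0
        assert imp.sum() == pytest.approx(1.0)

    def test_non_normalized_importance_rejected(self):
        with pytest.raises(ValueError):
            attention_regularization(Tensor(np.array([0.5, 0.5])), np.array([0.9, 0.5]))

    def test_one_hot_preset_selects_single_channel(self):
        rng = np.random.default_rng(0)
        reprs = [Tensor(rng.normal(size=(3, 8))) for _ in range(3)]
        w = Tensor(np.zeros((8, 1)))
        b = Tensor(np.zeros(1))
        # with a zero head, loss depends only on the target; one-hot mixing
        # must equal using channel 0 alone
        a = alignment_regularization(reprs, np.array([1.0, 0, 0]), np.zeros((3, 1)), w, b)
        b2 = alignment_regularization([reprs[0]] * 3, np.array([1/3, 1/3, 1/3]),
                                      np.zeros((3, 1)), w, b)
        assert a.data == pytest.approx(b2.data)

    def test_presets_match_documented_mapping(self):
        assert ALIGNMENT_PRESETS["mol_weight"].tolist() == [0.45, 0.1, 0.45]
        assert ALIGNMENT_PRESETS["scaffold_weight"].tolist() == [0.1, 0.45, 0.45]

    def test_off_simplex_preset_rejected(self):
        reprs = [Tensor(np.zeros((1, 4)))] * 3
        with pytest.raises(ValueError):
            alignment_regularization(reprs, np.array([0.5, 0.5, 0.5]),
                                     np.zeros((1, 1)), Tensor(np.zeros((4, 1))),
                                     Tensor(np.zeros(1)))


class TestOverallLoss:
    def test_arithmetic(self):
        assert overall_loss(1, 1, 1, 2).l_overall == pytest.approx(3.2)
        assert overall_loss(0, 0, 0, 0).l_overall == 0.0

    def test_regularization_scaling_linearity(self):
        base = overall_loss(0.3, 0.2, 0.1, 1.0).l_overall
        moved = overall_loss(0.3, 0.2, 0.1, 2.0).l_overall
        assert moved - base == pytest.approx(0.1)

    def test_breakdown_recombination_exact(self):
        b = overall_loss(0.123, 0.456, 0.789, 0.321)
        assert abs(b.l_overall - (b.l_mcd + b.l_scd + b.l_cp + 0.1 * b.l_regu)) < 1e-9
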