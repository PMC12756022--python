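"""DGA pooling, baselines, bag semantics and the gate degeneracy."""

import itertools

import numpy as np
import pytest

from habmil.autodiff import Tensor
from habmil.dga import (
    AttentionPooling,
    AttentionRecord,
    BagClassifier,
    DGAPooling,
    LSVDGate,
    MaxPooling,
    MeanPooling,
    TanhAttentionBranch,
    bag_label_rule,
    make_pooling,
)

DIM = 6


def bag(rng, n=5):
    return Tensor(rng.normal(size=(n, DIM)))


class TestBagLabelRule:
    def test_matches_logical_or_on_all_length4_vectors(self):
        for bits in itertools.product((0, 1), repeat=4):
            assert bag_label_rule(bits) == int(any(bits))

    def test_all_negative_instances_give_negative_bag(self):
        assert bag_label_rule([0, 0, 0, 0]) == 0

    def test_single_positive_instance_flips_the_bag(self):
        assert bag_label_rule([0, 1, 0]) == 1

    def test_empty_bag_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bag_label_rule([])

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            bag_label_rule([0, 2])


class TestTanhBranch:
    def test_zero_parameters_give_equal_scores(self, rng):
        br = TanhAttentionBranch(DIM, 4, 0.0, np.random.default_rng(0))
        for p in br.parameters():
            p.data = np.zeros_like(p.data)
        out = br(bag(rng)).data.ravel()
        np.testing.assert_allclose(out, out[0], atol=1e-12)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)  # tanh(0) = 0

    def test_scores_in_open_unit_interval(self, rng):
        br = TanhAttentionBranch(DIM, 4, 0.0, np.random.default_rng(1))
        out = br(bag(rng, 20)).data
        assert (out > -1).all() and (out < 1).all()

    def test_matches_per_instance_loop_in_eval_mode(self, rng):
        br = TanhAttentionBranch(DIM, 4, 0.5, np.random.default_rng(2))
        br.eval()
        x = rng.normal(size=(6, DIM))
        got = br(Tensor(x)).data.ravel()
        v, vb = br.lin1.weight.data, br.lin1.bias.data
        w, wb = br.lin2.weight.data, br.lin2.bias.data
        for i in range(6):
            expect = np.tanh((np.tanh(x[i] @ v + vb) @ w + wb).item())
            assert abs(got[i] - expect) < 1e-12


class TestLSVDGate:
    def test_zero_sigma_gives_half_gates(self, rng):
        gate = LSVDGate(DIM, 3, np.random.default_rng(0))
        gate.lsvd.sigma.data = np.zeros(3)
        out = gate(bag(rng)).data
        np.testing.assert_allclose(out, 0.5, atol=1e-12)

    def test_gates_strictly_inside_unit_interval(self, rng):
        gate = LSVDGate(DIM, 3, np.random.default_rng(1))
        out = gate(bag(rng, 12)).data
        assert (out > 0).all() and (out < 1).all()

    def test_matches_compositional_oracle(self, rng):
        gate = LSVDGate(DIM, 3, np.random.default_rng(2))
        x = rng.normal(size=(5, DIM))
        got = gate(Tensor(x)).data.ravel()
        from habmil.lsvd import lsvd_project, lsvd_reconstruct

        a_hat = lsvd_reconstruct(lsvd_project(x, gate.lsvd))
        expect = 1.0 / (1.0 + np.exp(-a_hat.mean(axis=1)))
        np.testing.assert_allclose(got, expect, atol=1e-12)


class TestDGAPool:
    def test_singleton_bag_passes_through(self, rng):
        pool = DGAPooling(DIM, np.random.default_rng(0), lsvd_rank=1)
        pool.eval()
        x = bag(rng, 1)
        z, rec = pool(x)
        np.testing.assert_allclose(rec.a_final, [1.0])
        np.testing.assert_allclose(z.data, x.data[0], atol=1e-12)

    def test_identical_instances_get_uniform_weights(self):
        pool = DGAPooling(DIM, np.random.default_rng(1), lsvd_rank=2)
        pool.eval()
        x = Tensor(np.tile(np.linspace(-1, 1, DIM), (4, 1)))
        z, rec = pool(x)
        np.testing.assert_allclose(rec.a_final, 0.25, atol=1e-12)
        np.testing.assert_allclose(z.data, x.data[0], atol=1e-12)

    def test_matches_explicit_weighted_sum(self, rng):
        pool = DGAPooling(DIM, np.random.default_rng(2), lsvd_rank=3)
        pool.eval()
        x = rng.normal(size=(7, DIM))
        z, rec = pool(Tensor(x))
        assert abs(rec.a_final.sum() - 1.0) < 1e-12
        expect = sum(rec.a_final[i] * x[i] for i in range(7))
        np.testing.assert_allclose(z.data, expect, atol=1e-12)
        assert ((rec.a_lsvd > 0) & (rec.a_lsvd < 1)).all()
        assert ((rec.a_tanh > -1) & (rec.a_tanh < 1)).all()

    def test_permutation_invariance_of_z(self, rng):
        pool = DGAPooling(DIM, np.random.default_rng(3), lsvd_rank=2)
        pool.eval()
        x = rng.normal(size=(6, DIM))
        perm = rng.permutation(6)
        z1, r1 = pool(Tensor(x))
        z2, r2 = pool(Tensor(x[perm]))
        np.testing.assert_allclose(z1.data, z2.data, atol=1e-10)
        np.testing.assert_allclose(r2.a_final, r1.a_final[perm], atol=1e-10)

    def test_empty_bag_rejected(self):
        pool = DGAPooling(DIM, np.random.default_rng(4), lsvd_rank=1)
        with pytest.raises(ValueError, match="empty"):
            pool(Tensor(np.zeros((0, DIM))))


class TestGateDegeneracy:
    def test_clamped_gate_equals_plain_attention_exactly(self, rng):
        """With a_lsvd forced to 1 and shared Tanh/score parameters, DGA is
        numerically identical to the plain attention baseline."""
        seed_rng = np.random.default_rng(7)
        dga = DGAPooling(DIM, seed_rng, lsvd_rank=2)
        dga.eval()
        dga.clamp_gate = True
        attn = AttentionPooling(DIM, np.random.default_rng(99))
        attn.eval()
        for src, dst in [(dga.branch, attn.branch), (dga.score, attn.score)]:
            dst.load_state_arrays(src.state_arrays())
        x = Tensor(rng.normal(size=(8, DIM)))
        z_dga, r_dga = dga(x)
        z_att, r_att = attn(x)
        np.testing.assert_allclose(z_dga.data, z_att.data, atol=1e-12)
        np.testing.assert_allclose(r_dga.a_final, r_att.a_final, atol=1e-12)


class TestBaselinePools:
    def test_mean_of_two_instances(self):
        pool = MeanPooling()
        u, v = np.arange(DIM, dtype=float), np.ones(DIM)
        z, rec = pool(Tensor(np.stack([u, v])))
        np.testing.assert_allclose(z.data, (u + v) / 2)
        np.testing.assert_allclose(rec.a_final, 0.5)

    def test_max_returns_the_dominating_instance(self, rng):
        pool = MaxPooling()
        x = rng.normal(size=(4, DIM))
        x[2] = x.max() + 1.0  # dominates every coordinate
        z, rec = pool(Tensor(x))
        np.testing.assert_allclose(z.data, x[2])
        assert rec.a_final.argmax() == 2

    def test_attention_weights_sum_to_one(self, rng):
        pool = AttentionPooling(DIM, np.random.default_rng(0))
        pool.eval()
        _, rec = pool(bag(rng, 9))
        assert abs(rec.a_final.sum() - 1.0) < 1e-12

    @pytest.mark.parametrize("kind", ["max", "mean", "attention", "dga"])
    def test_factory_builds_each_kind(self, kind):
        pool = make_pooling(kind, DIM, np.random.default_rng(0))
        assert pool.kind == kind

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="pooling"):
            make_pooling("median", DIM, np.random.default_rng(0))


class TestBagClassifier:
    def test_zero_head_gives_half_probability(self, rng):
        clf = BagClassifier(DIM, np.random.default_rng(0))
        for p in clf.parameters():
            p.data = np.zeros_like(p.data)
        pred = clf.classify(rng.normal(size=DIM))
        assert pred.probability == 0.5
        assert pred.predicted_label == 1  # threshold is inclusive

    def test_probability_monotone_in_logit(self):
        clf = BagClassifier(1, np.random.default_rng(1))
        clf.head.weight.data = np.array([[1.0]])
        clf.head.bias.data = np.array([0.0])
        probs = [clf.classify(np.array([v])).probability for v in (-2, 0, 2)]
        assert probs[0] < probs[1] < probs[2]

    def test_attention_record_requires_normalized_weights(self):
        with pytest.raises(ValueError, match="sum to 1"):
            AttentionRecord(None, None, np.array([0.5, 0.2]), np.zeros(2))
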