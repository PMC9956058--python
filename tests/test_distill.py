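"""The softmax fusion pair, the four-scale pooled L2 losses and the weighted
total objective."""

import numpy as np
import pytest

from distilharvest import nn
from distilharvest.distill import (Distiller, DistillWeights, SKFuse,
                                   StagePairing, multiscale_l2, sk_fuse,
                                   total_loss)
from distilharvest.errors import ConfigurationError
from distilharvest.nn import Tensor


class TestSKFuse:
    def test_equal_matrices_give_arithmetic_mean(self, rng):
        fuse = SKFuse(4, rng=np.random.default_rng(0))
        fuse.B.weight.data = fuse.A.weight.data.copy()
        b1 = Tensor(rng.random((2, 4, 6, 6)))
        b2 = Tensor(rng.random((2, 4, 6, 6)))
        fused, a, b = fuse(b1, b2)
        assert np.allclose(a.data, 0.5)
        assert np.allclose(fused.data, (b1.data + b2.data) / 2, atol=1e-6)

    def test_scalar_softmax_pair_by_hand(self):
        # AZ = ln 2, BZ = 0  ->  a = 2/3, b = 1/3
        az, bz = np.log(2.0), 0.0
        a = np.exp(az) / (np.exp(az) + np.exp(bz))
        b = np.exp(bz) / (np.exp(az) + np.exp(bz))
        assert np.isclose(a, 2 / 3) and np.isclose(b, 1 / 3)
        # the module reproduces the same arithmetic through its matrices
        fuse = SKFuse(1, descriptor_dim=1, rng=np.random.default_rng(0))
        fuse.fc.weight.data = np.array([[1.0], [1.0]], dtype=np.float32)
        fuse.fc.bias.data = np.array([1.0], dtype=np.float32) \
            - fuse.fc.weight.data.sum()  # force Z = 1 for unit inputs
        fuse.A.weight.data = np.array([[np.log(2.0)]], dtype=np.float32)
        fuse.B.weight.data = np.array([[0.0]], dtype=np.float32)
        ones = Tensor(np.ones((1, 1, 2, 2), dtype=np.float32))
        _, a_t, b_t = fuse(ones, ones)
        assert np.isclose(float(a_t.data.squeeze()), 2 / 3, atol=1e-6)
        assert np.isclose(float(b_t.data.squeeze()), 1 / 3, atol=1e-6)

    def test_weights_sum_to_one_for_random_states(self, rng):
        for trial in range(5):
            fuse = SKFuse(8, rng=np.random.default_rng(trial))
            b1 = Tensor(rng.standard_normal((3, 8, 4, 4)))
            b2 = Tensor(rng.standard_normal((3, 8, 4, 4)))
            _, a, b = fuse(b1, b2)
            assert np.abs(a.data + b.data - 1.0).max() < 1e-6
            assert (a.data > 0).all() and (b.data > 0).all()

    def test_fewer_than_two_maps_rejected(self, rng):
        fuse = SKFuse(4)
        with pytest.raises(ConfigurationError):
            sk_fuse([Tensor(rng.random((1, 4, 2, 2)))], fuse)


class TestMultiscaleL2:
    def test_identical_features_give_zero(self, rng):
        fm = Tensor(rng.random((2, 3, 8, 8)))
        assert float(multiscale_l2(fm, fm).data) == 0.0

    def test_ones_vs_zeros_single_scale(self):
        t = Tensor(np.ones((1, 1, 2, 2)))
        s = Tensor(np.zeros((1, 1, 2, 2)))
        assert np.isclose(float(multiscale_l2(t, s, scales=(1,)).data), 1.0)

    def test_quadratic_homogeneity(self, rng):
        t = Tensor(rng.random((1, 2, 8, 8)))
        s = Tensor(rng.random((1, 2, 8, 8)))
        base = float(multiscale_l2(t, s).data)
        scaled = float(multiscale_l2(t * 3.0, s * 3.0).data)
        assert np.isclose(scaled, 9.0 * base, rtol=1e-5)

    def test_symmetry_and_nonnegativity(self, rng):
        t = Tensor(rng.random((1, 2, 8, 8)))
        s = Tensor(rng.random((1, 2, 8, 8)))
        assert np.isclose(float(multiscale_l2(t, s).data),
                          float(multiscale_l2(s, t).data))
        assert float(multiscale_l2(t, s).data) >= 0

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ConfigurationError):
            multiscale_l2(Tensor(rng.random((1, 2, 8, 8))),
                          Tensor(rng.random((1, 3, 8, 8))))


class TestTotalLoss:
    def test_study_weights_unit_fixture(self):
        # TtL = (1,1,1,1), Lobj = 0: 0.1 + 0.2 + 0.5 + 0.2 = 1.0
        total, bd = total_loss([1.0, 1.0, 1.0, 1.0], 0.0)
        assert np.isclose(float(total.data), 1.0)
        assert bd.weights.as_tuple() == (0.1, 0.2, 0.5, 0.2)

    def test_all_zero(self):
        total, _ = total_loss([0, 0, 0, 0], 0.0)
        assert float(total.data) == 0.0

    def test_projection_weight(self):
        total, _ = total_loss([3.7, 9, 9, 9], 0.0,
                              DistillWeights(1.0, 0.0, 0.0, 0.0))
        assert np.isclose(float(total.data), 3.7)

    def test_decomposition_identity_random(self, rng):
        for _ in range(10):
            ttls = rng.random(4)
            lobj = rng.random()
            total, bd = total_loss(list(ttls), lobj)
            assert bd.identity_residual() < 1e-9
            assert np.isclose(float(total.data), bd.total)

    def test_negative_weight_rejected(self):
        with pytest.raises(ConfigurationError):
            total_loss([1, 1, 1, 1], 0.0, DistillWeights(alpha=-0.1))


@pytest.fixture(scope="module")
def nets():
    from distilharvest.detnet import NetworkSpec, build_network
    t = build_network(NetworkSpec(role="teacher", backbone="cspdarknet",
                                  input_side=96, width_multiple=0.25,
                                  depth_multiple=0.33, dropout=0.0))
    s = build_network(NetworkSpec(role="student", backbone="mobilenetv2",
                                  input_side=96, width_multiple=0.25,
                                  depth_multiple=0.33, dropout=0.0))
    t.eval()
    s.eval()
    return t, s


class TestDistiller:
    def _taps(self, nets):
        t, s = nets
        probe = np.zeros((1, 3, 96, 96), dtype=np.float32)
        with nn.no_grad():
            _, tt = t.forward_with_taps(probe)
            _, ts = s.forward_with_taps(probe)
        return tt, ts

    def test_four_stage_losses_nonnegative(self, nets, rng):
        tt, ts = self._taps(nets)
        d = Distiller(tt, ts, seed=0)
        t, s = nets
        x = rng.random((2, 3, 96, 96)).astype(np.float32)
        with nn.no_grad():
            _, tap_t = t.forward_with_taps(x)
            _, tap_s = s.forward_with_taps(x)
        losses = d.stage_losses(tap_t, tap_s)
        assert len(losses) == 4
        assert all(float(l.data) >= 0 for l in losses)

    def test_unknown_tap_rejected(self, nets):
        tt, ts = self._taps(nets)
        bad = StagePairing(stages=[(["backbone.p9"], "backbone.p5"),
                                   (["neck.n1"], "neck.n1"),
                                   (["neck.n2"], "neck.n2"),
                                   (["head.out3"], "head.out3")])
        with pytest.raises(ConfigurationError):
            Distiller(tt, ts, pairing=bad)

    def test_teacher_receives_no_gradient(self, nets, rng):
        """Gradient flow contract: distillation updates must never touch the
        teacher's parameters."""
        from distilharvest.distill import distill_step
        t, s = nets
        tt, ts = self._taps(nets)
        d = Distiller(tt, ts, seed=0)
        x = rng.random((1, 3, 96, 96)).astype(np.float32)
        objs = [[(0, 0.5, 0.5, 0.4, 0.6)]]
        total, bd, _ = distill_step(t, s, d, x, x, objs, DistillWeights())
        total.backward()
        assert all(p.grad is None for p in t.parameters())
        assert any(p.grad is not None for p in s.parameters())
        assert bd.identity_residual() < 1e-6
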