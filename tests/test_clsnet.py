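"""Gated channel transformation and the classification backbone."""
import numpy as np
import pytest

from vertemtl import nn
from vertemtl.clsnet import (EMBED_DIM, CascadeFuse, ClsNet, ClsNetConfig,
                             GatedResidualBlock, GCTParams, gct)
from vertemtl.nn import Tensor


class TestGct:
    def test_identity_at_zero_gamma_beta(self, rng):
        x = rng.normal(size=(2, 5, 4, 4)).astype(np.float32)
        p = GCTParams.create(5)
        out = gct(Tensor(x), p).data
        assert np.array_equal(out, x)

    def test_zero_alpha_gate_is_one_plus_tanh_beta(self, rng):
        x = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
        p = GCTParams.create(3)
        p.alpha.data[:] = 0.0
        p.beta.data[:] = np.array([0.5, -0.5, 0.0], np.float32)
        out = gct(Tensor(x), p).data
        for c, b in enumerate([0.5, -0.5, 0.0]):
            assert np.allclose(out[0, c], x[0, c] * (1 + np.tanh(b)), atol=1e-5)

    def test_hand_computed_two_channel_example(self):
        # 2-channel 1x1 input (3, 4): s = (3, 4),
        # s_hat = sqrt(2)*(3, 4)/5, gate = 1 + tanh(s_hat)
        x = np.array([3.0, 4.0], np.float32).reshape(1, 2, 1, 1)
        p = GCTParams(Tensor(np.ones(2, np.float32), requires_grad=True),
                      Tensor(np.ones(2, np.float32), requires_grad=True),
                      Tensor(np.zeros(2, np.float32), requires_grad=True),
                      eps=0.0, norm_eps=0.0)
        out = gct(Tensor(x), p).data.ravel()
        s_hat = np.sqrt(2.0) * np.array([3.0, 4.0]) / 5.0
        expected = np.array([3.0, 4.0]) * (1.0 + np.tanh(s_hat))
        assert np.allclose(out, expected, rtol=1e-5)

    def test_gate_factor_strictly_inside_zero_two(self, rng):
        for _ in range(10):
            x = rng.normal(size=(2, 4, 3, 3)).astype(np.float32) * 10
            p = GCTParams.create(4)
            p.gamma.data[:] = rng.normal(size=4).astype(np.float32)
            p.beta.data[:] = rng.normal(size=4).astype(np.float32)
            out = gct(Tensor(x), p).data
            nz = np.abs(x) > 1e-6
            ratio = out[nz] / x[nz]
            assert ratio.min() > 0.0 and ratio.max() < 2.0

    def test_normalized_embedding_sum_of_squares_is_channel_count(self, rng):
        c = 6
        x = rng.normal(size=(3, c, 5, 5)).astype(np.float64)
        sq = (x ** 2).sum(axis=(2, 3))
        s = np.sqrt(sq)  # alpha = 1, eps = 0
        s_hat = np.sqrt(c) * s / np.sqrt((s ** 2).sum(axis=1, keepdims=True))
        assert np.allclose((s_hat ** 2).sum(axis=1), c, atol=1e-9)

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            gct(Tensor(rng.normal(size=(1, 3, 2, 2)).astype(np.float32)),
                GCTParams.create(4))


class TestGatedResidualBlock:
    def test_zero_convs_identity_shortcut_preserve_nonneg_input(self, rng):
        block = GatedResidualBlock(np.random.default_rng(0), 3, 3)
        for conv in (block.body.conv1, block.body.conv2):
            conv.weight.data[:] = 0.0
        x = np.abs(rng.normal(size=(1, 3, 4, 4))).astype(np.float32)
        out = block(Tensor(x)).data
        assert np.allclose(out, x, atol=1e-6)

    def test_finite_output_for_random_input(self, rng):
        block = GatedResidualBlock(np.random.default_rng(1), 4, 8, stride=2)
        out = block(Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32) * 100))
        assert np.all(np.isfinite(out.data))

    def test_gamma_receives_gradient(self, rng):
        block = GatedResidualBlock(np.random.default_rng(2), 3, 3)
        x = Tensor(rng.normal(size=(1, 3, 4, 4)).astype(np.float32))
        (block(x) ** 2.0).mean().backward()
        g = block.gct_params.gamma.grad
        assert g is not None and np.abs(g).max() > 0

    def test_gct_disabled_matches_plain_residual(self, rng):
        b1 = GatedResidualBlock(np.random.default_rng(3), 3, 3, use_gct=True)
        b2 = GatedResidualBlock(np.random.default_rng(3), 3, 3, use_gct=False)
        x = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
        # gamma = beta = 0 at init: the gate is exactly the identity
        assert np.allclose(b1(Tensor(x)).data, b2(Tensor(x)).data, atol=1e-6)


class TestCascadeFuse:
    def test_identity_initialized_conv_returns_y(self, rng):
        fuse = CascadeFuse(np.random.default_rng(0), y_ch=3, s_ch=2)
        w = np.zeros((3, 5, 1, 1), np.float32)
        for i in range(3):
            w[i, i, 0, 0] = 1.0
        fuse.conv.weight.data[:] = w
        fuse.conv.bias.data[:] = 0.0
        y = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
        s = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        assert np.allclose(fuse(Tensor(y), Tensor(s)).data, y, atol=1e-6)

    def test_output_channels_match_y(self, rng):
        fuse = CascadeFuse(np.random.default_rng(0), y_ch=5, s_ch=3)
        out = fuse(Tensor(rng.normal(size=(2, 5, 4, 4)).astype(np.float32)),
                   Tensor(rng.normal(size=(2, 3, 4, 4)).astype(np.float32)))
        assert out.data.shape == (2, 5, 4, 4)

    def test_both_inputs_receive_gradient(self, rng):
        fuse = CascadeFuse(np.random.default_rng(0), y_ch=2, s_ch=2)
        y = Tensor(rng.normal(size=(1, 2, 3, 3)).astype(np.float32),
                   requires_grad=True)
        s = Tensor(rng.normal(size=(1, 2, 3, 3)).astype(np.float32),
                   requires_grad=True)
        (fuse(y, s) ** 2.0).mean().backward()
        assert np.abs(y.grad).max() > 0 and np.abs(s.grad).max() > 0

    def test_spatial_mismatch_raises(self, rng):
        fuse = CascadeFuse(np.random.default_rng(0), y_ch=2, s_ch=2)
        with pytest.raises(ValueError):
            fuse(Tensor(np.zeros((1, 2, 4, 4), np.float32)),
                 Tensor(np.zeros((1, 2, 8, 8), np.float32)))


class TestClsNet:
    @pytest.mark.parametrize("width", [4, 8])
    def test_embedding_is_always_2048(self, width, rng):
        net = ClsNet(np.random.default_rng(0),
                     ClsNetConfig(base_width=width, cascade_stages=(),
                                  seg_channels=()))
        x = Tensor(rng.random((2, 1, 64, 64)).astype(np.float32))
        assert net(x).data.shape == (2, EMBED_DIM)

    def test_eval_mode_deterministic(self, rng):
        net = ClsNet(np.random.default_rng(0),
                     ClsNetConfig(cascade_stages=(), seg_channels=())).eval()
        x = Tensor(rng.random((1, 1, 64, 64)).astype(np.float32))
        e1, e2 = net(x).data, net(x).data
        assert np.array_equal(e1, e2)

    def test_cascade_features_change_embedding(self, rng):
        net = ClsNet(np.random.default_rng(0),
                     ClsNetConfig(base_width=4, cascade_stages=(0,),
                                  seg_channels=(2,))).eval()
        x = Tensor(rng.random((1, 1, 64, 64)).astype(np.float32))
        s = Tensor(rng.random((1, 2, 64, 64)).astype(np.float32))
        e_with = net(x, [s]).data
        e_zero = net(x, [Tensor(np.zeros((1, 2, 64, 64), np.float32))]).data
        assert not np.allclose(e_with, e_zero)
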