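"""Equation-level oracles for the bespoke blocks: Prewitt edge magnitudes,
CSPP composition, dynamic-convolution attention and mixing, and the
channel/spatial attention of CPCA."""

import numpy as np
import pytest

from prunedet.nn import Tensor, no_grad, cat, max_pool2d
from prunedet.blocks import (prewitt_filter, PREWITT_GX, PREWITT_GY, CSPP,
                             DynamicConv2d, C3k2, CPCA, ConvBNAct)

rng = np.random.default_rng(7)


def nested_loop_correlate(img, kernel, pad_mode="constant"):
    """Brute-force padded cross-correlation of one 2-D channel."""
    h, w = img.shape
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(img, ((ph, ph), (pw, pw)), mode=pad_mode)
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = (padded[i:i + kh, j:j + kw] * kernel).sum()
    return out


class TestPrewitt:
    def test_constant_input_zero_response(self):
        x = Tensor(np.full((1, 2, 5, 5), 3.7, dtype=np.float32))
        y = prewitt_filter(x)
        np.testing.assert_allclose(y.data, 0, atol=1e-6)

    def test_center_impulse_has_zero_center_response(self):
        x = np.zeros((1, 1, 3, 3), dtype=np.float32)
        x[0, 0, 1, 1] = 1.0
        y = prewitt_filter(Tensor(x))
        assert y.data[0, 0, 1, 1] == pytest.approx(0, abs=1e-6)

    def test_vertical_step_matches_nested_loop_oracle(self):
        img = np.array([[0, 0, 1, 1]] * 4, dtype=np.float32)
        y = prewitt_filter(Tensor(img[None, None])).data[0, 0]
        gx = nested_loop_correlate(img, PREWITT_GX, "edge")
        gy = nested_loop_correlate(img, PREWITT_GY, "edge")
        np.testing.assert_allclose(y, np.sqrt(gx ** 2 + gy ** 2), atol=1e-5)

    def test_random_inputs_match_oracle(self):
        for _ in range(20):
            img = rng.normal(size=(6, 7)).astype(np.float32)
            y = prewitt_filter(Tensor(img[None, None])).data[0, 0]
            gx = nested_loop_correlate(img, PREWITT_GX, "edge")
            gy = nested_loop_correlate(img, PREWITT_GY, "edge")
            np.testing.assert_allclose(y, np.sqrt(gx ** 2 + gy ** 2),
                                       atol=1e-4)

    def test_nonnegative_and_transpose_symmetry(self):
        img = rng.normal(size=(1, 1, 8, 8)).astype(np.float32)
        y = prewitt_filter(Tensor(img)).data
        yt = prewitt_filter(Tensor(img.transpose(0, 1, 3, 2))).data
        assert (y >= 0).all()
        np.testing.assert_allclose(yt, y.transpose(0, 1, 3, 2), atol=1e-5)

    def test_too_small_input_raises(self):
        with pytest.raises(ValueError):
            prewitt_filter(Tensor(np.zeros((1, 1, 2, 2))))


class TestCSPP:
    def test_output_shape_halves_spatial(self):
        blk = CSPP(1, 16, 8, 12, rng=np.random.default_rng(0))
        blk.eval()
        with no_grad():
            y = blk(Tensor(np.zeros((1, 1, 64, 64), dtype=np.float32)))
        assert y.data.shape == (1, 16, 32, 32)

    def test_composition_matches_manual_pipeline(self):
        blk = CSPP(1, 8, 4, 6, rng=np.random.default_rng(1))
        blk.eval()
        x = Tensor(rng.normal(size=(1, 1, 8, 8)).astype(np.float32))
        with no_grad():
            y = blk(x)
            x1 = blk.cv1(x)
            manual = blk.cv3(blk.cv2(cat([prewitt_filter(x1),
                                          max_pool2d(x1, 3, 1, 1)], axis=1)))
        np.testing.assert_allclose(y.data, manual.data, atol=1e-6)


class TestDynamicConv:
    def test_zero_fc_weights_give_uniform_attention(self):
        dc = DynamicConv2d(2, 2, 3, K=4, rng=np.random.default_rng(0))
        for t in (dc.fc1_w, dc.fc1_b, dc.fc2_w, dc.fc2_b):
            t.data[:] = 0
        theta = dc.attention(Tensor(rng.normal(size=(3, 2, 4, 4)))).data
        np.testing.assert_allclose(theta, 0.25, atol=1e-7)

    def test_attention_rows_sum_to_one(self):
        dc = DynamicConv2d(3, 5, 3, K=3, rng=np.random.default_rng(2))
        theta = dc.attention(Tensor(rng.normal(size=(4, 3, 5, 5)))).data
        assert (theta >= 0).all()
        np.testing.assert_allclose(theta.sum(axis=1), 1.0, atol=1e-6)

    def test_attention_matches_direct_arithmetic(self):
        dc = DynamicConv2d(2, 2, 1, K=2, rng=np.random.default_rng(3))
        dc.fc1_w.data = np.array([[1.0, -0.5], [0.25, 0.75]], dtype=np.float32)
        dc.fc1_b.data = np.array([0.1, -0.2], dtype=np.float32)
        dc.fc2_w.data = np.array([[0.3, 0.6], [-0.4, 0.2]], dtype=np.float32)
        dc.fc2_b.data = np.array([0.05, 0.0], dtype=np.float32)
        x = np.full((1, 2, 3, 3), 0.0, dtype=np.float32)
        x[0, 0] = 2.0
        x[0, 1] = -1.0
        g = np.array([2.0, -1.0])
        h = np.maximum(dc.fc1_w.data @ g + dc.fc1_b.data, 0)
        logits = dc.fc2_w.data @ h + dc.fc2_b.data
        e = np.exp(logits - logits.max())
        expected = e / e.sum()
        theta = dc.attention(Tensor(x)).data[0]
        np.testing.assert_allclose(theta, expected, atol=1e-6)

    def test_one_hot_theta_equals_static_conv(self):
        from prunedet.nn import conv2d
        dc = DynamicConv2d(3, 4, 3, K=3, rng=np.random.default_rng(4))
        x = Tensor(rng.normal(size=(2, 3, 6, 6)).astype(np.float32))
        for j in range(3):
            dc.fc2_b.data[:] = -1e4
            dc.fc2_b.data[j] = 1e4       # force one-hot attention on kernel j
            with no_grad():
                y = dc(x)
                ref = conv2d(x, Tensor(dc.weight.data[j]), None, 1, 1)
            np.testing.assert_allclose(y.data, ref.data, atol=1e-4)

    def test_zero_bank_zero_output_and_1x1_matrix_oracle(self):
        dc = DynamicConv2d(2, 2, 1, K=2, rng=np.random.default_rng(5))
        x = Tensor(rng.normal(size=(2, 2, 1, 1)).astype(np.float32))
        saved = dc.weight.data.copy()
        dc.weight.data[:] = 0
        with no_grad():
            np.testing.assert_allclose(dc(x).data, 0, atol=1e-7)
        dc.weight.data = saved
        with no_grad():
            theta = dc.attention(x).data             # (2, 2)
            y = dc(x).data
        for n in range(2):
            w = (theta[n, :, None, None, None, None] * dc.weight.data).sum(0)
            expected = w[:, :, 0, 0] @ x.data[n, :, 0, 0]
            np.testing.assert_allclose(y[n, :, 0, 0], expected, atol=1e-5)

    def test_sigmoid_attention_gates_independently(self):
        dc = DynamicConv2d(2, 2, 3, K=3, attention_norm="sigmoid",
                           rng=np.random.default_rng(8))
        theta = dc.attention(Tensor(rng.normal(size=(4, 2, 5, 5)))).data
        assert ((theta > 0) & (theta < 1)).all()
        with pytest.raises(ValueError):
            DynamicConv2d(2, 2, attention_norm="tanh")

    def test_batch_entries_use_their_own_theta(self):
        dc = DynamicConv2d(2, 3, 3, K=2, rng=np.random.default_rng(6))
        xa = rng.normal(size=(1, 2, 5, 5)).astype(np.float32)
        xb = rng.normal(size=(1, 2, 5, 5)).astype(np.float32)
        with no_grad():
            ya = dc(Tensor(xa)).data
            yb = dc(Tensor(xb)).data
            yab = dc(Tensor(np.concatenate([xa, xb]))).data
        np.testing.assert_allclose(yab[0], ya[0], atol=1e-5)
        np.testing.assert_allclose(yab[1], yb[0], atol=1e-5)


class TestDCC:
    def test_k1_bank_matches_static_block(self):
        r1, r2 = np.random.default_rng(11), np.random.default_rng(11)
        static = C3k2(16, 16, 1, dynamic=False, rng=r1)
        dyn = C3k2(16, 16, 1, dynamic=True, K=1, rng=r2)
        # same kernels: copy the static bottleneck weights into the K=1 bank
        for st, dy in ((static.m[0].cv1, dyn.m[0].cv1),
                       (static.m[0].cv2, dyn.m[0].cv2)):
            dy.conv.weight.data = st.conv.weight.data[None].copy()
            dy.bn.weight.data = st.bn.weight.data.copy()
            dy.bn.bias.data = st.bn.bias.data.copy()
        for name in ("cv1", "cv2"):
            getattr(dyn, name).conv.weight.data = \
                getattr(static, name).conv.weight.data.copy()
        static.eval(); dyn.eval()
        x = Tensor(rng.normal(size=(2, 16, 8, 8)).astype(np.float32))
        with no_grad():
            np.testing.assert_allclose(dyn(x).data, static(x).data, atol=1e-5)

    @pytest.mark.parametrize("c", [32, 64])
    def test_channel_parity(self, c):
        blk = C3k2(c, c, 1, dynamic=True, K=2, rng=np.random.default_rng(0))
        blk.eval()
        with no_grad():
            y = blk(Tensor(np.zeros((1, c, 8, 8), dtype=np.float32)))
        assert y.data.shape == (1, c, 8, 8)

    def test_composition_matches_manual_subblocks(self):
        blk = C3k2(16, 16, 1, dynamic=True, K=2, rng=np.random.default_rng(1))
        blk.eval()
        x = Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32))
        with no_grad():
            y = blk(x)
            t = blk.cv1(x)
            a, b = t[:, :8], t[:, 8:]
            m = blk.m[0](b)
            manual = blk.cv2(cat([a, b, m], axis=1))
        np.testing.assert_allclose(y.data, manual.data, atol=1e-6)


class TestCPCA:
    def test_zero_mlp_gives_half_channel_attention(self):
        p = CPCA(4, rng=np.random.default_rng(0))
        for t in (p.mlp1.weight, p.mlp1.bias, p.mlp2.weight, p.mlp2.bias):
            t.data[:] = 0
        mc = p.channel_attention(Tensor(rng.normal(size=(2, 4, 5, 5)))).data
        np.testing.assert_allclose(mc, 0.5, atol=1e-7)

    def test_channel_attention_in_open_unit_interval(self):
        p = CPCA(8, rng=np.random.default_rng(1))
        mc = p.channel_attention(Tensor(rng.normal(size=(2, 8, 6, 6)))).data
        assert mc.shape == (2, 8, 1, 1)
        assert ((mc > 0) & (mc < 1)).all()

    def test_constant_map_channel_attention_closed_form(self):
        """avg == max for constants, so CA = sigma(2 * MLP(v))."""
        p = CPCA(2, reduction=1, rng=np.random.default_rng(2))
        v = np.array([0.7, -0.3], dtype=np.float32)
        x = np.broadcast_to(v[None, :, None, None], (1, 2, 4, 4)).copy()
        mc = p.channel_attention(Tensor(x)).data[0, :, 0, 0]
        w1 = p.mlp1.weight.data[:, :, 0, 0]
        b1 = p.mlp1.bias.data
        w2 = p.mlp2.weight.data[:, :, 0, 0]
        b2 = p.mlp2.bias.data
        mlp = w2 @ np.maximum(w1 @ v + b1, 0) + b2
        np.testing.assert_allclose(mc, 1 / (1 + np.exp(-2 * mlp)), atol=1e-6)

    def test_spatial_attention_identity_branch_ablation(self):
        p = CPCA(3, rng=np.random.default_rng(3))
        for m in p.strips:
            m.weight.data[:] = 0
            m.bias.data[:] = 0
        p.mix.weight.data[:] = np.eye(3)[:, :, None, None]
        p.mix.bias.data[:] = 0
        x = Tensor(rng.normal(size=(1, 3, 6, 6)).astype(np.float32))
        ms = p.spatial_attention(x).data
        np.testing.assert_allclose(ms, p.dw5(x).data, atol=1e-6)

    @pytest.mark.parametrize("hw", [(1, 1), (3, 9), (9, 9)])
    def test_spatial_attention_shape_preserving(self, hw):
        p = CPCA(4, rng=np.random.default_rng(4))
        x = Tensor(np.zeros((1, 4, *hw), dtype=np.float32))
        assert p.spatial_attention(x).data.shape == (1, 4, *hw)

    def test_spatial_attention_matches_nested_loop_oracle(self):
        p = CPCA(4, rng=np.random.default_rng(5))
        x = rng.normal(size=(1, 4, 9, 9)).astype(np.float32)
        ms = p.spatial_attention(Tensor(x)).data[0]
        # oracle: depthwise correlations computed by explicit loops
        def dw(img, kernel, bias):
            out = np.zeros((4, 9, 9))
            for c in range(4):
                out[c] = nested_loop_correlate(img[c], kernel[c, 0]) + bias[c]
            return out
        d = dw(x[0], p.dw5.weight.data, p.dw5.bias.data)
        total = d.copy()
        for i in range(0, len(p.strips), 2):
            a = dw(d, p.strips[i].weight.data, p.strips[i].bias.data)
            b = dw(a, p.strips[i + 1].weight.data, p.strips[i + 1].bias.data)
            total += b
        mixed = np.einsum("oc,chw->ohw", p.mix.weight.data[:, :, 0, 0], total) \
            + p.mix.bias.data[:, None, None]
        np.testing.assert_allclose(ms, mixed, atol=1e-4)

    def test_forward_identity_and_zero_gating(self):
        p = CPCA(3, rng=np.random.default_rng(6))
        zero = Tensor(np.zeros((1, 3, 5, 5), dtype=np.float32))
        np.testing.assert_allclose(p(zero).data, 0, atol=1e-6)
        x = Tensor(rng.normal(size=(2, 3, 5, 5)).astype(np.float32))
        mc = p.channel_attention(x)
        fc = mc * x
        ms = p.spatial_attention(fc)
        np.testing.assert_allclose(p(x).data, (ms * mc * x).data, atol=1e-6)


def test_batch_order_equivariance():
    """Permuting batch entries permutes outputs identically (all blocks)."""
    blocks = [
        CSPP(1, 8, 4, 6, rng=np.random.default_rng(0)),
        C3k2(8, 8, 1, dynamic=True, K=2, rng=np.random.default_rng(1)),
        CPCA(8, rng=np.random.default_rng(2)),
    ]
    perm = [2, 0, 1]
    for blk in blocks:
        blk.eval()
        c_in = 1 if isinstance(blk, CSPP) else 8
        x = rng.normal(size=(3, c_in, 8, 8)).astype(np.float32)
        with no_grad():
            y = blk(Tensor(x)).data
            yp = blk(Tensor(x[perm])).data
        np.testing.assert_allclose(yp, y[perm], atol=1e-5)
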