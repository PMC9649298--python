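"""Atrous convolution, DAC, MKP and bottleneck-fusion contracts.

The dilated convolution is validated against an explicit-loop
dilated-correlation oracle; pooling against exhaustive window
enumeration.
"""

import numpy as np
import pytest

from mcunet import tensor as T
from mcunet.context import (BottleneckFusion, DACBlock, DilationSpec,
                            MKPBlock, PoolingSpec, atrous_conv2d)


def dilated_correlation_oracle(x, w, rate, pad):
    """Explicit loops over every output position: y[i] = sum_k x[i + r k] w[k]."""
    B, C, H, W = x.shape
    O, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((B, O, H, W))
    for b in range(B):
        for o in range(O):
            for i in range(H):
                for j in range(W):
                    acc = 0.0
                    for c in range(C):
                        for ki in range(kh):
                            for kj in range(kw):
                                acc += (xp[b, c, i + rate * ki, j + rate * kj]
                                        * w[o, c, ki, kj])
                    out[b, o, i, j] = acc
    return out


class TestAtrousConv:
    def test_rate1_identity_kernel_is_identity(self, rng):
        w = np.zeros((2, 2, 3, 3))
        w[0, 0, 1, 1] = 1.0
        w[1, 1, 1, 1] = 1.0
        x = rng.standard_normal((1, 2, 8, 8))
        out = atrous_conv2d(x, w, rate=1)
        np.testing.assert_allclose(out.data, x, atol=1e-14)

    def test_1d_worked_example(self):
        """x=[1,2,3,4,5], w=[1,1,1], r=2, zero padding 2 -> [4,6,9,6,8]."""
        x = np.array([1.0, 2, 3, 4, 5]).reshape(1, 1, 1, 5)
        w = np.ones((1, 1, 1, 3))
        out = T.conv2d(T.Tensor(x), T.Tensor(w), padding=(0, 2), dilation=2)
        np.testing.assert_array_equal(out.data.ravel(), [4, 6, 9, 6, 8])

    def test_matches_loop_oracle_on_random_instances(self, rng):
        for _ in range(25):
            C = int(rng.integers(1, 4))
            O = int(rng.integers(1, 3))
            H, W = int(rng.integers(5, 9)), int(rng.integers(5, 9))
            rate = int(rng.integers(1, 4))
            x = rng.standard_normal((1, C, H, W))
            w = rng.standard_normal((O, C, 3, 3))
            out = atrous_conv2d(x, w, rate=rate)
            expect = dilated_correlation_oracle(x, w, rate, rate)
            np.testing.assert_allclose(out.data, expect, atol=1e-5)

    def test_rate1_bitwise_equals_standard_convolution(self, rng):
        x = rng.standard_normal((1, 3, 8, 8))
        w = rng.standard_normal((4, 3, 3, 3))
        a = atrous_conv2d(x, w, rate=1).data
        b = T.conv2d(T.Tensor(x), T.Tensor(w), padding=1, dilation=1).data
        np.testing.assert_array_equal(a, b)

    def test_impulse_support_at_rate5(self):
        """A 3x3 filter at r=5 responds on an 11x11 effective field."""
        x = np.zeros((1, 1, 21, 21))
        x[0, 0, 10, 10] = 1.0
        w = np.ones((1, 1, 3, 3))
        out = atrous_conv2d(x, w, rate=5).data[0, 0]
        ys, xs = np.nonzero(out)
        taps = {10 - 5, 10, 10 + 5}
        assert set(ys) == taps and set(xs) == taps
        assert ys.max() - ys.min() + 1 == 11
        assert xs.max() - xs.min() + 1 == 11

    def test_even_kernel_raises_config_error(self, rng):
        with pytest.raises(ValueError, match="odd kernel"):
            atrous_conv2d(rng.random((1, 1, 4, 4)),
                          rng.random((1, 1, 2, 2)), rate=1)


class TestDAC:
    def test_default_rates_yield_four_branches(self):
        assert DilationSpec((1, 3, 5)).branches() == [
            (1,), (3,), (1, 3), (1, 3, 5)]

    @pytest.mark.parametrize("channels", [1, 3, 8])
    def test_shape_preserved(self, rng, channels):
        blk = DACBlock(channels, rng=rng)
        x = rng.random((1, channels, 8, 8))
        assert blk(x).shape == x.shape

    def test_zero_branch_weights_give_residual_identity(self, rng):
        blk = DACBlock(3, rng=rng)
        for p in blk.parameters():
            p.data[...] = 0.0
        x = rng.random((1, 3, 8, 8))
        np.testing.assert_allclose(blk(x).data, x, atol=1e-14)

    def test_single_branch_identity_kernel_doubles_input(self, rng):
        blk = DACBlock(1, branches=[(1,)], rng=rng)
        conv = blk.branch_convs[0][0]
        conv.weight.data[...] = 0.0
        conv.weight.data[0, 0, 1, 1] = 1.0
        conv.bias.data[...] = 0.0
        x = rng.random((1, 1, 6, 6))  # non-negative, ReLU transparent
        np.testing.assert_allclose(blk(x).data, 2 * x, atol=1e-14)

    def test_too_small_extents_raise(self, rng):
        blk = DACBlock(2, rng=rng)
        with pytest.raises(ValueError, match="too small"):
            blk(rng.random((1, 2, 4, 4)))


class TestMKP:
    def test_channel_arithmetic(self, rng):
        blk = MKPBlock(16, rng=rng)
        out = blk(rng.random((1, 16, 48, 48)))
        assert out.shape == (1, 16 + 4, 48, 48)

    def test_constant_input_unit_conv_appends_constants(self, rng):
        blk = MKPBlock(1, rng=rng)
        for conv in blk.squeeze:
            conv.weight.data[...] = 1.0
            conv.bias.data[...] = 0.0
        out = blk(np.full((1, 1, 12, 12), 3.0))
        np.testing.assert_allclose(out.data, 3.0)

    def test_worked_4x4_pooling_example(self, rng):
        """Values 1..16 row-major, kernel 2 stride 2 -> [[6,8],[14,16]]."""
        d = np.arange(1.0, 17.0).reshape(1, 1, 4, 4)
        pooled = T.max_pool2d(T.Tensor(d), 2).data[0, 0]
        np.testing.assert_array_equal(pooled, [[6, 8], [14, 16]])
        # brute-force window enumeration
        expect = np.array([[d[0, 0, i:i + 2, j:j + 2].max()
                            for j in (0, 2)] for i in (0, 2)])
        np.testing.assert_array_equal(pooled, expect)
        blk = MKPBlock(1, PoolingSpec((2,)), rng=rng)
        blk.squeeze[0].weight.data[...] = 1.0
        blk.squeeze[0].bias.data[...] = 0.0
        out = blk(d)
        np.testing.assert_array_equal(out.data[0, 1],
                                      np.repeat(np.repeat(pooled, 2, 0), 2, 1))

    def test_upsampled_maps_piecewise_constant_over_cells(self, rng):
        blk = MKPBlock(2, PoolingSpec((3,)), rng=rng)
        out = blk(rng.random((1, 2, 9, 9))).data[0, 2]
        for i in range(3):
            for j in range(3):
                cell = out[3 * i:3 * i + 3, 3 * j:3 * j + 3]
                assert np.all(cell == cell[0, 0])

    def test_kernel_larger_than_extents_raises(self, rng):
        blk = MKPBlock(1, rng=rng)  # kernels up to 6
        with pytest.raises(ValueError, match="exceeds"):
            blk(rng.random((1, 1, 5, 5)))

    def test_non_divisible_extents_use_ceil_mode(self, rng):
        blk = MKPBlock(1, rng=rng)
        out = blk(rng.random((1, 1, 48, 48)))  # 48 not divisible by 5
        assert out.shape == (1, 5, 48, 48)


class TestBottleneckFusion:
    def test_concat_width_bookkeeping(self, rng):
        fuse = BottleneckFusion(128, rng=rng)
        # SA(128) + MKP(DAC(128)) = 128 + 132 = 260 before reduction
        assert fuse.reduce.weight.shape == (128, 260, 3, 3)
        out = fuse(rng.random((1, 128, 8, 8)))
        assert out.shape == (1, 128, 8, 8)

    def test_backbone_degenerates_to_attention_alone(self, rng):
        fuse = BottleneckFusion(8, use_dac=False, use_mkp=False, rng=rng)
        assert fuse.dac is None and fuse.mkp is None
        assert fuse.reduce.weight.shape == (8, 8, 3, 3)
        out = fuse(rng.random((1, 8, 8, 8)))
        assert out.shape == (1, 8, 8, 8)

    def test_sum_mode_without_branches_raises(self, rng):
        with pytest.raises(ValueError, match="sum fusion"):
            BottleneckFusion(8, use_dac=False, use_mkp=False,
                             fusion_mode="sum", rng=rng)

    def test_composition_of_individually_tested_parts(self, rng):
        """With attention and context weights zeroed: SA = F/2 and the MKP
        channels carry the pooled raw F values."""
        fuse = BottleneckFusion(4, use_dac=True, use_mkp=True, rng=rng)
        fuse.attention.conv.weight.data[...] = 0.0
        fuse.attention.conv.bias.data[...] = 0.0
        for br in fuse.dac.branch_convs:
            for conv in br:
                conv.weight.data[...] = 0.0
                conv.bias.data[...] = 0.0
        for conv in fuse.dac.branch_projs:
            if conv is not None:
                conv.weight.data[...] = 0.0
                conv.bias.data[...] = 0.0
        f = rng.random((1, 4, 12, 12))
        sa, att = fuse.attention(f)
        np.testing.assert_allclose(sa.data, 0.5 * f)
        branch = fuse.mkp(fuse.dac(f))
        # DAC with zero branches is identity, so MKP consumed the raw F
        np.testing.assert_allclose(branch.data[:, :4], f)
        expect = fuse.reduce(T.concat([sa, branch], axis=1)).data
        np.testing.assert_allclose(fuse(f).data, expect)
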