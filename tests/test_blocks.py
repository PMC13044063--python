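"""Activations, SE attention, residual blocks and the counting formulas."""

import numpy as np
import pytest

from garlicnet.blocks import (
    BlockSpec,
    ConvSpec,
    ResidualBlock,
    SEBlock,
    conv_macs,
    conv_params,
)
from garlicnet.nn.functional import ACTIVATIONS, get_activation, sigmoid, silu


class TestActivations:
    def test_sigmoid_values(self):
        assert sigmoid(0.0) == 0.5
        assert np.isclose(sigmoid(1.0), 1.0 / (1.0 + np.exp(-1.0)))
        assert sigmoid(60.0) == pytest.approx(1.0)
        assert sigmoid(-60.0) == pytest.approx(0.0, abs=1e-20)

    def test_silu_values(self):
        # SiLU(0) = 0 * sigma(0) = 0 by definition
        assert silu(0.0) == 0.0
        assert np.isclose(silu(1.0), 1.0 / (1.0 + np.exp(-1.0)))
        assert np.isclose(silu(-1.0), -1.0 + 1.0 / (1.0 + np.exp(-1.0)))

    def test_silu_limits(self):
        x = np.array([-50.0, 50.0])
        y = silu(x)
        assert y[0] == pytest.approx(0.0, abs=1e-12)   # -> 0 at -inf
        assert y[1] == pytest.approx(50.0)             # -> x at +inf

    def test_silu_gradient_matches_closed_form(self):
        """Numeric gradient equals sigma(x) + x sigma(x)(1-sigma(x)) on a
        1000-point grid, confirming smoothness everywhere (incl. x=0)."""
        _, df = get_activation("silu")
        x = np.linspace(-10.0, 10.0, 1000)
        h = 1e-6
        numeric = (silu(x + h) - silu(x - h)) / (2 * h)
        s = sigmoid(x)
        analytic = s + x * s * (1 - s)
        assert np.allclose(numeric, analytic, atol=1e-6)
        assert np.allclose(df(x), analytic)

    @pytest.mark.parametrize("name", sorted(ACTIVATIONS))
    def test_every_activation_has_consistent_derivative(self, name, rng):
        f, df = get_activation(name)
        # avoid the non-differentiable kinks of the piecewise functions
        x = rng.uniform(-8, 8, size=256)
        x = x[np.min(np.abs(x[:, None] - np.array([-3.0, 0.0, 3.0, 6.0])),
                     axis=1) > 1e-2]
        h = 1e-6
        numeric = (f(x + h) - f(x - h)) / (2 * h)
        assert np.allclose(df(x), numeric, atol=1e-5)

    def test_unknown_activation_rejected(self):
        with pytest.raises(ValueError):
            get_activation("swishish")


class TestCountingFormulas:
    def test_standard_conv_params(self):
        assert conv_params(ConvSpec(3, 64, 64)) == 36_864
        assert conv_params(ConvSpec(1, 1, 1)) == 1

    def test_depthwise_conv_params(self):
        assert conv_params(ConvSpec(3, 64, 64, depthwise=True)) == 576

    def test_standard_conv_macs(self):
        assert conv_macs(ConvSpec(3, 64, 64), 56, 56) == 115_605_504
        assert conv_macs(ConvSpec(1, 1, 1), 1, 1) == 1

    def test_depthwise_conv_macs(self):
        assert conv_macs(ConvSpec(3, 64, 64, depthwise=True),
                         56, 56) == 1_806_336

    def test_depthwise_requires_matching_channels(self):
        with pytest.raises(ValueError):
            ConvSpec(3, 8, 16, depthwise=True)

    def test_counts_match_brute_force_enumeration(self):
        """Exhaustive loop-count oracle over small specs (K<=3, C<=8)."""
        def brute_params(K, cin, cout, dw):
            n = 0
            kernels = range(cin) if dw else range(cout)
            for _k in kernels:
                chans = 1 if dw else cin
                for _c in range(chans):
                    for _i in range(K):
                        for _j in range(K):
                            n += 1
            return n

        def brute_macs(K, cin, cout, dw, H, W):
            n = 0
            for _h in range(H):
                for _w in range(W):
                    outs = range(cin) if dw else range(cout)
                    for _o in outs:
                        chans = 1 if dw else cin
                        for _c in range(chans):
                            n += K * K
                    # one multiply per kernel tap, accumulated above
            return n

        for K in (1, 3):
            for cin in (1, 3, 8):
                for cout in (1, 4, 8):
                    spec = ConvSpec(K, cin, cout)
                    assert conv_params(spec) == brute_params(K, cin, cout,
                                                             False)
                    for H, W in ((1, 1), (5, 7), (8, 8)):
                        assert conv_macs(spec, H, W) == brute_macs(
                            K, cin, cout, False, H, W)
                spec = ConvSpec(K, cin, cin, depthwise=True)
                assert conv_params(spec) == brute_params(K, cin, cin, True)
                assert conv_macs(spec, 8, 8) == brute_macs(K, cin, cin, True,
                                                           8, 8)

    def test_macs_match_instrumented_multiply_count(self, rng):
        """Counting actual scalar multiplies of a naive sliding-window conv
        reproduces the closed form on a tiny 3-channel case."""
        K, cin, cout, H, W = 3, 3, 2, 4, 4
        x = rng.normal(size=(cin, H + 2, W + 2))  # pre-padded
        w = rng.normal(size=(cout, cin, K, K))
        multiplies = 0
        for o in range(cout):
            for i in range(H):
                for j in range(W):
                    acc = 0.0
                    for c in range(cin):
                        for a in range(K):
                            for b in range(K):
                                acc += w[o, c, a, b] * x[c, i + a, j + b]
                                multiplies += 1
        assert multiplies == conv_macs(ConvSpec(K, cin, cout), H, W)


def _identity_bn(bn):
    """Make a batch-norm layer the identity in eval mode."""
    bn.gamma.data[...] = 1.0
    bn.beta.data[...] = 0.0
    bn.running_mean[...] = 0.0
    bn.running_var[...] = 1.0 - bn.eps


def _basic_spec(c_in, c_out, stride=1, **kw):
    conv1 = ConvSpec(3, c_in, c_out, stride)
    conv2 = ConvSpec(3, c_out, c_out, 1, kw.pop("depthwise", False))
    proj = (ConvSpec(1, c_in, c_out, stride)
            if stride > 1 or c_in != c_out else None)
    return BlockSpec(conv1=conv1, conv2=conv2, projection=proj, **kw)


class TestSEBlock:
    def test_gates_scale_channels_and_preserve_shape(self, rng):
        x = rng.normal(size=(2, 6, 5, 5))
        se = SEBlock(6, reduction=2, rng=rng)
        y = se.forward(x)
        assert y.shape == x.shape
        # every output channel is g_c * input channel with g_c in (0, 1)
        g = y[0, :, 0, 0] / x[0, :, 0, 0]
        assert np.all((g > 0) & (g < 1))
        assert np.allclose(y[0], g[:, None, None] * x[0])

    def test_identity_gate_bias_trick(self, rng):
        x = rng.normal(size=(1, 4, 3, 3))
        se = SEBlock(4, reduction=2, rng=rng)
        se.fc2.weight.data[...] = 0.0
        se.fc2.bias.data[...] = 40.0  # sigmoid(40) ~= 1
        assert np.allclose(se.forward(x), x, atol=1e-12)

    def test_zero_input_gives_zero_output(self):
        se = SEBlock(4, reduction=2)
        assert np.all(se.forward(np.zeros((1, 4, 3, 3))) == 0.0)

    def test_reduction_floor_keeps_one_hidden_unit(self):
        se = SEBlock(3, reduction=16)
        assert se.fc1.weight.data.shape == (1, 3)


class TestResidualBlock:
    def test_zero_branch_reduces_to_activated_identity(self, rng):
        spec = _basic_spec(4, 4)
        blk = ResidualBlock(spec, rng=rng)
        blk.conv1.weight.data[...] = 0.0
        blk.conv2.weight.data[...] = 0.0
        for bn in (blk.bn1, blk.bn2):
            _identity_bn(bn)
        blk.eval()
        x = np.abs(rng.normal(size=(1, 4, 6, 6)))  # non-negative input
        y = blk.forward(x)
        assert np.allclose(y, x)

    def test_projection_block_halves_spatial_and_doubles_channels(self, rng):
        blk = ResidualBlock(_basic_spec(8, 16, stride=2), rng=rng)
        blk.eval()
        y = blk.forward(rng.normal(size=(2, 8, 16, 16)))
        assert y.shape == (2, 16, 8, 8)

    def test_stride_one_preserves_spatial_dims(self, rng):
        blk = ResidualBlock(_basic_spec(8, 8), rng=rng)
        blk.eval()
        assert blk.forward(rng.normal(size=(1, 8, 9, 9))).shape == (1, 8, 9, 9)

    def test_odd_input_halves_by_ceil_division(self, rng):
        blk = ResidualBlock(_basic_spec(4, 8, stride=2), rng=rng)
        blk.eval()
        assert blk.forward(rng.normal(size=(1, 4, 9, 9))).shape == (1, 8, 5, 5)

    def test_nested_equals_plain_when_branch_is_zero(self, rng):
        x = np.abs(np.random.default_rng(3).normal(size=(1, 4, 6, 6)))
        outs = []
        for nested in (False, True):
            blk = ResidualBlock(_basic_spec(4, 4, nested=nested),
                                rng=np.random.default_rng(0))
            blk.conv1.weight.data[...] = 0.0
            blk.conv2.weight.data[...] = 0.0
            for bn in (blk.bn1, blk.bn2):
                _identity_bn(bn)
            blk.eval()
            outs.append(blk.forward(x))
        assert np.allclose(outs[0], outs[1])

    def test_channel_mismatch_rejected(self, rng):
        blk = ResidualBlock(_basic_spec(4, 4), rng=rng)
        with pytest.raises(ValueError):
            blk.forward(rng.normal(size=(1, 6, 6, 6)))

    def test_projection_invariant_enforced(self):
        with pytest.raises(ValueError):
            BlockSpec(conv1=ConvSpec(3, 4, 8, 2), conv2=ConvSpec(3, 8, 8))

    def test_se_preserves_shape_inside_block(self, rng):
        blk = ResidualBlock(_basic_spec(6, 6, use_se=True, se_reduction=2),
                            rng=rng)
        blk.eval()
        assert blk.forward(rng.normal(size=(1, 6, 5, 5))).shape == (1, 6, 5, 5)

    def test_matches_textbook_block_reference(self, rng):
        """Golden comparison: plain ReLU block (no SE, no nesting, identity
        BN) equals an independent loop-based conv reference on fixed input."""
        c, H = 3, 6
        blk = ResidualBlock(_basic_spec(c, c), rng=rng)
        for bn in (blk.bn1, blk.bn2):
            _identity_bn(bn)
        blk.eval()
        x = np.random.default_rng(42).normal(size=(1, c, H, H))

        def ref_conv(xin, w):  # stride 1, pad 1 cross-correlation
            cin, hh, ww = xin.shape
            cout = w.shape[0]
            xp = np.pad(xin, ((0, 0), (1, 1), (1, 1)))
            out = np.zeros((cout, hh, ww))
            for o in range(cout):
                for i in range(hh):
                    for j in range(ww):
                        out[o, i, j] = np.sum(
                            w[o] * xp[:, i:i + 3, j:j + 3])
            return out

        relu = lambda a: np.maximum(a, 0.0)
        branch = ref_conv(relu(ref_conv(x[0], blk.conv1.weight.data)),
                          blk.conv2.weight.data)
        expected = relu(branch + x[0])
        assert np.allclose(blk.forward(x)[0], expected, atol=1e-10)
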