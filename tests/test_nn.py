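"""Layer-level checks: analytic gradients vs. central differences, the
attention block's contract, initialization statistics, and checkpoints."""

import numpy as np
import pytest

from nodulefusion.nn import (
    AttentionResidualBlock,
    BatchNorm,
    Conv,
    MaxPool,
    BranchNetwork,
    build_network,
    channel_attention_weights,
    kaiming_init,
    load_checkpoint,
    save_checkpoint,
)


def numerical_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestGradients:
    @pytest.mark.parametrize(
        "dim, in_shape, stride",
        [(2, (2, 3, 7, 6), 2), (2, (2, 2, 5, 5), 1), (3, (2, 2, 5, 6, 5), 2)],
    )
    def test_conv_gradients_match_central_differences(self, rng, dim, in_shape, stride):
        conv = Conv(in_shape[1], 4, 3, dim, stride=stride)
        conv.weight.value[...] = rng.normal(size=conv.weight.value.shape)
        conv.bias.value[...] = rng.normal(size=4)
        x = rng.normal(size=in_shape)
        proj = rng.normal(size=conv.forward(x).shape)

        def loss():
            return float((conv.forward(x) * proj).sum())

        loss()
        conv.zero_grad()
        gx = conv.backward(proj)
        np.testing.assert_allclose(gx, numerical_grad(loss, x), atol=1e-6)
        np.testing.assert_allclose(
            conv.weight.grad, numerical_grad(loss, conv.weight.value), atol=1e-6
        )

    def test_batchnorm_training_gradient(self, rng):
        bn = BatchNorm(3)
        bn.gamma.value[...] = rng.uniform(0.5, 1.5, 3)
        bn.beta.value[...] = rng.normal(size=3)
        x = rng.normal(size=(4, 3, 5, 5))
        proj = rng.normal(size=x.shape)

        def loss():
            return float((bn.forward(x) * proj).sum())

        loss()
        bn.zero_grad()
        gx = bn.backward(proj)
        np.testing.assert_allclose(gx, numerical_grad(loss, x), atol=1e-5)

    def test_maxpool_routes_gradient_to_argmax(self, rng):
        pool = MaxPool((2, 2))
        x = rng.normal(size=(1, 1, 4, 4))
        y = pool.forward(x)
        gx = pool.backward(np.ones_like(y))
        # gradient mass lands exactly on the four window maxima
        assert gx.sum() == 4.0
        assert np.count_nonzero(gx) == 4
        np.testing.assert_array_equal(np.sort(x[gx > 0]), np.sort(y.ravel()))

    def test_attention_block_full_gradient(self, rng):
        blk = AttentionResidualBlock(2, 3, kernel_size=3, dim=2, stride=2)
        for p in blk.parameters():
            p.value[...] = rng.normal(size=p.value.shape) * 0.5
        x = rng.normal(size=(3, 2, 6, 6))
        proj = rng.normal(size=(3, 3, 3, 3))

        def loss():
            blk.set_training(True)
            return float((blk.forward(x) * proj).sum())

        loss()
        blk.zero_grad()
        gx = blk.backward(proj)
        np.testing.assert_allclose(gx, numerical_grad(loss, x), atol=1e-5)
        for p in blk.parameters():
            np.testing.assert_allclose(
                p.grad, numerical_grad(loss, p.value), atol=1e-5, err_msg=p.name
            )


class TestAttentionWeights:
    def _block(self, channels=1):
        blk = AttentionResidualBlock(channels, channels, dim=2)
        blk.set_training(False)
        return blk

    def test_zeroed_attention_params_give_zero_weights(self, rng):
        blk = self._block(4)
        x_f = rng.normal(size=(2, 4, 5, 5))
        assert np.all(channel_attention_weights(x_f, blk) == 0.0)

    def test_identity_maps_with_half_bias_give_unit_weights(self):
        blk = self._block(2)
        for lin in (blk.f_m, blk.f_a):
            lin.weight.value[...] = 0.0
            lin.bias.value[...] = 0.5
        x_f = np.zeros((1, 2, 3, 3))
        np.testing.assert_allclose(channel_attention_weights(x_f, blk), 1.0)

    def test_max_plus_mean_with_identity_maps(self):
        # single-channel map [[1,3],[5,7]]: max 7, mean 4 -> weight 11
        blk = self._block(1)
        for lin in (blk.f_m, blk.f_a):
            lin.weight.value[...] = 1.0
            lin.bias.value[...] = 0.0
        x_f = np.array([[[[1.0, 3.0], [5.0, 7.0]]]])
        np.testing.assert_allclose(channel_attention_weights(x_f, blk), [[11.0]])

    def test_weights_are_nonnegative_for_random_params(self, rng):
        blk = self._block(8)
        for p in blk.parameters():
            p.value[...] = rng.normal(size=p.value.shape)
        for _ in range(20):
            w = channel_attention_weights(rng.normal(size=(3, 8, 4, 4)), blk)
            assert np.all(w >= 0.0)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="channels"):
            channel_attention_weights(rng.normal(size=(1, 5, 4, 4)), self._block(4))


class TestBlockForward:
    def test_zeroed_attention_path_reduces_to_direct_connection(self, rng):
        blk = AttentionResidualBlock(2, 2, dim=2)
        for p in blk.parameters():
            p.value[...] = rng.normal(size=p.value.shape)
        for lin in (blk.f_m, blk.f_a):
            lin.weight.value[...] = 0.0
            lin.bias.value[...] = 0.0
        blk.set_training(False)
        x = rng.normal(size=(2, 2, 8, 8))
        expected = blk.direct_bn(blk.direct_conv(x))
        np.testing.assert_allclose(blk.forward(x), expected)

    def test_pure_residual_identity(self):
        # conv-transform zeroed, direct path = identity conv with inference BN
        blk = AttentionResidualBlock(1, 1, dim=2)
        blk.direct_conv.weight.value[...] = 1.0
        blk.set_training(False)
        x = np.arange(8.0).reshape(1, 1, 2, 4)
        np.testing.assert_allclose(blk.forward(x), x, atol=1e-3)

    def test_hand_worked_forward_on_2x2_input(self):
        """Tiny single-channel forward pass against a by-hand evaluation.

        Unit 1x1 convs everywhere, inference-mode BN as identity
        (eps-corrected), conv-transform = x, attention weight
        = relu(max) + relu(mean).
        """
        blk = AttentionResidualBlock(1, 1, kernel_size=1, dim=2)
        blk.conv1.weight.value[...] = 1.0
        blk.conv2.weight.value[...] = 1.0
        blk.direct_conv.weight.value[...] = 1.0
        for lin in (blk.f_m, blk.f_a):
            lin.weight.value[...] = 1.0
            lin.bias.value[...] = 0.0
        blk.set_training(False)
        x = np.array([[[[1.0, 2.0], [3.0, 4.0]]]])
        # X_F = x (relu passes: all positive); weight = relu(4) + relu(2.5) = 6.5
        # y = direct(x) + 6.5 * X_F = x + 6.5 x = 7.5 x, up to the BN eps shrink
        np.testing.assert_allclose(blk.forward(x), 7.5 * x, rtol=1e-4)


class TestNetwork:
    def test_feature_vector_length_is_256_both_dims(self, rng):
        for dim, shape in ((2, (4, 3, 32, 32)), (3, (4, 1, 7, 32, 32))):
            net = kaiming_init(build_network(dim, channels=(4, 8, 256)), rng)
            logit, feat = net.forward(rng.normal(size=shape))
            assert logit.shape == (4,)
            assert feat.shape == (4, 256)

    def test_last_block_must_emit_256_channels(self):
        with pytest.raises(ValueError, match="256"):
            BranchNetwork(dim=2, channels=(8, 16, 32))

    def test_inference_forward_is_deterministic(self, rng):
        net = kaiming_init(build_network(2, channels=(4, 8, 256)), rng)
        net.set_training(False)
        x = rng.normal(size=(2, 3, 32, 32))
        l1, f1 = net.forward(x)
        l2, f2 = net.forward(x)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(f1, f2)

    def test_kaiming_init_statistics(self):
        rng = np.random.default_rng(0)
        conv = Conv(64, 128, 3, 2)
        from nodulefusion.nn.layers import kaiming_normal_

        kaiming_normal_(conv.weight, conv.fan_in, rng)
        target = 2.0 / (64 * 9)
        assert abs(conv.weight.value.var() / target - 1.0) < 0.1
        net = build_network(2, channels=(4, 8, 256))
        kaiming_init(net, np.random.default_rng(1))
        assert np.all(net.stem_bn.gamma.value == 1.0)
        assert np.all(net.stem_bn.beta.value == 0.0)

    def test_kaiming_init_is_seed_deterministic(self):
        nets = [
            kaiming_init(build_network(2, channels=(4, 8, 256)), np.random.default_rng(5))
            for _ in range(2)
        ]
        for p1, p2 in zip(nets[0].parameters(), nets[1].parameters()):
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        net = kaiming_init(build_network(3, channels=(4, 8, 256)), rng)
        net.set_training(False)
        x = rng.normal(size=(2, 1, 7, 32, 32))
        logit, feat = net.forward(x)
        save_checkpoint(net, tmp_path / "ckpt.npz")
        net2 = load_checkpoint(tmp_path / "ckpt.npz")
        logit2, feat2 = net2.forward(x)
        np.testing.assert_array_equal(logit, logit2)
        np.testing.assert_array_equal(feat, feat2)
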