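"""Network blocks: receptive field, recalibration, gating, decoder, forward."""

import numpy as np
import pytest

import vesselseg as vs
from vesselseg import nn
from vesselseg.errors import InvalidConfigError, InvalidInputError, InvalidShapeError
from vesselseg.model import (MSIEBlock, SEBlock, TransferLayer, DecoderStep,
                             decoder_step, feature_reweight, global_average_pool,
                             msie_block, transfer_layer)

from _oracles import (dilated_kernel_dense, feature_reweight_loop,
                      global_average_pool_loop, transfer_layer_loop)

rng = np.random.default_rng(5)


def make_se(channels=4, reduction=2, seed=0):
    params = {}
    return SEBlock(np.random.default_rng(seed), channels, reduction, "se", params)


def make_transfer(channels=4, out_ch=None, seed=0):
    params = {}
    return TransferLayer(np.random.default_rng(seed), channels,
                         out_ch or channels, "tl", params)


class TestEffectiveKernelSize:
    def test_rate_2_equals_5x5(self):
        assert vs.effective_kernel_size(3, 2) == 5

    def test_rate_1_is_standard_convolution(self):
        assert vs.effective_kernel_size(3, 1) == 3

    def test_rate_4(self):
        assert vs.effective_kernel_size(3, 4) == 9

    def test_nonpositive_arguments_rejected(self):
        for k, r in [(0, 1), (3, 0), (-1, 2)]:
            with pytest.raises(InvalidConfigError):
                vs.effective_kernel_size(k, r)

    @pytest.mark.parametrize("rate", [1, 2, 4])
    def test_gradient_support_probe_matches_formula(self, rate):
        """Brute-force receptive field of one dilated layer equals K."""
        assert vs.receptive_field_support(3, rate) == \
            vs.effective_kernel_size(3, rate)


class TestGlobalAveragePool:
    def test_constant_map(self):
        X = np.full((3, 5, 2), 4.2)
        np.testing.assert_allclose(global_average_pool(X),
                                   np.full((1, 1, 2), 4.2))

    def test_2x2_arithmetic_mean(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        assert global_average_pool(X)[0, 0, 0] == pytest.approx(2.5)

    def test_matches_double_loop_oracle(self):
        X = rng.random((8, 8, 4))
        np.testing.assert_allclose(global_average_pool(X).ravel(),
                                   global_average_pool_loop(X), atol=1e-12)

    def test_empty_map_rejected(self):
        with pytest.raises(InvalidInputError):
            global_average_pool(np.zeros((0, 4, 2)))


class TestFeatureReweight:
    def test_zero_transform_halves_input(self):
        """sigmoid(0) = 1/2, so zeroed recalibration weights scale X by 0.5."""
        se = make_se()
        for p in (se.w1, se.b1, se.w2, se.b2):
            p.data[...] = 0.0
        X = rng.random((5, 5, 4))
        np.testing.assert_allclose(feature_reweight(X, se), 0.5 * X, atol=1e-12)

    def test_zero_input_stays_zero(self):
        se = make_se()
        X = np.zeros((6, 6, 4))
        np.testing.assert_array_equal(feature_reweight(X, se), X)

    def test_matches_loop_oracle(self):
        se = make_se(channels=4, reduction=2, seed=3)
        X = rng.random((8, 8, 4))
        np.testing.assert_allclose(feature_reweight(X, se),
                                   feature_reweight_loop(X, se), atol=1e-10)

    def test_never_amplifies_magnitudes(self):
        """Gate in (0,1) implies |U| <= |X| elementwise."""
        se = make_se(seed=9)
        X = rng.normal(size=(7, 7, 4))
        U = feature_reweight(X, se)
        assert np.all(np.abs(U) <= np.abs(X) + 1e-15)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(InvalidConfigError):
            feature_reweight(rng.random((4, 4, 3)), make_se(channels=4))


class TestTransferLayer:
    def test_zero_weights_quarter_input_before_projection(self):
        """Two zeroed sigmoid gates each contribute a factor 1/2."""
        tl = make_transfer()
        for name in ("cmax", "cmean", "smax", "smean"):
            getattr(tl, f"{name}_w").data[...] = 0.0
            getattr(tl, f"{name}_b").data[...] = 0.0
        X = rng.random((6, 6, 4))
        t = nn.Tensor(X.transpose(2, 0, 1)[None])
        alpha, beta, y = tl.gates(t, "combined")
        np.testing.assert_allclose(alpha.data, 0.5)
        np.testing.assert_allclose(beta.data, 0.5)
        np.testing.assert_allclose(y.data[0].transpose(1, 2, 0), 0.25 * X,
                                   atol=1e-12)

    def test_zero_input_gives_bias_only_output(self):
        tl = make_transfer()
        X = np.zeros((5, 5, 4))
        out = transfer_layer(X, tl)
        expected = np.broadcast_to(tl.out_b.data, out.shape)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    @pytest.mark.parametrize("gate_mode", ["combined", "literal"])
    def test_matches_loop_oracle(self, gate_mode):
        tl = make_transfer(seed=4)
        X = rng.random((8, 8, 4))
        np.testing.assert_allclose(transfer_layer(X, tl, gate_mode),
                                   transfer_layer_loop(X, tl, gate_mode),
                                   atol=1e-10)

    def test_gates_strictly_inside_unit_interval(self):
        tl = make_transfer(seed=8)
        t = nn.Tensor(rng.normal(size=(1, 4, 6, 6)))
        alpha, beta, _ = tl.gates(t)
        for g in (alpha.data, beta.data):
            assert np.all(g > 0.0) and np.all(g < 1.0)

    def test_unknown_gate_mode_rejected(self):
        with pytest.raises(InvalidConfigError):
            transfer_layer(rng.random((4, 4, 4)), make_transfer(), "bogus")


class TestMSIEBlock:
    def _block(self, rates=(1, 2, 4, 8), in_ch=3, out_ch=6, seed=0):
        return MSIEBlock(np.random.default_rng(seed), in_ch, out_ch,
                         rates, 2, "msie", {})

    @pytest.mark.parametrize("rates", [(1, 2, 4, 8), (1, 3, 5, 7)])
    def test_spatial_dims_preserved(self, rates):
        block = self._block(rates=rates)
        X = rng.random((11, 13, 3))
        assert msie_block(X, block).shape == (11, 13, 6)

    def test_degenerate_rates_make_branches_identical(self):
        """With all rates 1 and shared weights, the 4 dilated branches agree."""
        block = self._block(rates=(1, 1, 1, 1))
        w0, b0 = block.branches[0]
        for w, b in block.branches[1:]:
            w.data[...] = w0.data
            b.data[...] = b0.data
        x = nn.Tensor(rng.random((1, 3, 7, 7)))
        outs = [nn.conv2d(x, w, b, dilation=r).data
                for (w, b), r in zip(block.branches, block.rates)]
        for o in outs[1:]:
            np.testing.assert_array_equal(o, outs[0])

    def test_dilated_branch_equals_zero_inserted_dense_kernel(self):
        """Each dilated branch is the claimed K x K convolution in disguise."""
        from scipy.signal import correlate2d
        block = self._block(in_ch=1, out_ch=2, seed=2)
        x = rng.random((1, 1, 7, 7))
        for (w, b), r in zip(block.branches, block.rates):
            got = nn.conv2d(nn.Tensor(x), w, nn.Tensor(np.zeros(2)),
                            dilation=r).data
            for o in range(2):
                dense = dilated_kernel_dense(w.data[o, 0], r)
                ref = correlate2d(x[0, 0], dense, mode="same")
                np.testing.assert_allclose(got[0, o], ref, atol=1e-12)

    def test_dilation_adds_no_kernel_parameters(self):
        """A dilated 3x3 branch keeps 9 weights per channel pair; its dense
        K x K equivalent would need K^2."""
        block = self._block()
        for (w, _), r in zip(block.branches, block.rates):
            assert w.data.shape[-2:] == (3, 3)
            K = vs.effective_kernel_size(3, r)
            dense_count = w.data.shape[0] * w.data.shape[1] * K * K
            assert w.data.size == w.data.shape[0] * w.data.shape[1] * 9
            if r > 1:
                assert dense_count > w.data.size


class TestDecoderStep:
    def _step(self, deep_ch=8, skip_ch=4, out_ch=4):
        return DecoderStep(np.random.default_rng(0), deep_ch, skip_ch,
                           out_ch, "dec", {})

    def test_8x8_deep_with_16x16_skip_gives_16x16(self):
        out = decoder_step(rng.random((8, 8, 8)), rng.random((16, 16, 4)),
                           self._step())
        assert out.shape == (16, 16, 4)

    def test_mismatched_resolution_rejected(self):
        with pytest.raises(InvalidShapeError):
            decoder_step(rng.random((8, 8, 8)), rng.random((20, 20, 4)),
                         self._step())

    def test_concatenated_channels_are_sum_of_contributions(self):
        step = self._step()
        assert step.c1_w.data.shape[1] == 4 + 4  # upsampled + skip widths


class TestBFCNForward:
    CFG = vs.ModelConfig(depth=3, base_channels=8, seed=0)

    def test_128x128_patch_gives_128x128_probability_map(self):
        model = vs.BFCN(self.CFG)
        out = vs.bfcn_forward(rng.random((128, 128)), model)
        assert out.shape == (128, 128)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_outputs_within_unit_interval(self):
        model = vs.BFCN(self.CFG)
        out = model.predict(rng.random((3, 32, 32)) * 5.0)
        assert np.all((out >= 0.0) & (out <= 1.0))

    def test_indivisible_input_rejected_with_padding_hint(self):
        model = vs.BFCN(self.CFG)
        with pytest.raises(InvalidShapeError, match="pad"):
            model.predict(rng.random((33, 33)))

    def test_forward_deterministic(self):
        model = vs.BFCN(self.CFG)
        x = rng.random((32, 32))
        np.testing.assert_array_equal(model.predict(x), model.predict(x))

    def test_every_parameter_receives_gradient(self):
        """Some input must reach every weight: no dead branches by design."""
        model = vs.BFCN(vs.ModelConfig(depth=3, base_channels=8, seed=1))
        for k, p in model.params.items():
            if k.endswith(".b"):
                p.data += 0.01  # move pre-activations off the ReLU kink
        got = {k: 0.0 for k in model.params}
        local = np.random.default_rng(0)
        for trial in range(3):
            x = nn.Tensor(local.random((1, 1, 16, 16)))
            y = (local.random((1, 1, 16, 16)) > 0.8).astype(float)
            prob = model.forward(x)
            loss = nn.bce_loss(prob, y)
            for p in model.params.values():
                p.grad = None
            loss.backward()
            for k, p in model.params.items():
                if p.grad is not None:
                    got[k] = max(got[k], np.abs(p.grad).max())
        dead = [k for k, v in got.items() if v == 0.0]
        assert not dead, f"parameters with zero gradient: {dead}"

    def test_gate_modes_give_different_but_valid_outputs(self):
        x = rng.random((32, 32))
        out_c = vs.BFCN(vs.ModelConfig(depth=2, base_channels=4, seed=2,
                                       gate_mode="combined")).predict(x)
        out_l = vs.BFCN(vs.ModelConfig(depth=2, base_channels=4, seed=2,
                                       gate_mode="literal")).predict(x)
        assert out_c.shape == out_l.shape == (32, 32)
        assert not np.array_equal(out_c, out_l)

    def test_checkpoint_roundtrip(self, tmp_path):
        model = vs.BFCN(vs.ModelConfig(depth=2, base_channels=4, seed=3))
        x = rng.random((16, 16))
        before = model.predict(x)
        vs.save_checkpoint(model, tmp_path / "ckpt")
        reloaded = vs.load_checkpoint(tmp_path / "ckpt")
        np.testing.assert_array_equal(before, reloaded.predict(x))

    def test_dilation_rates_must_be_4_distinct(self):
        with pytest.raises(InvalidConfigError):
            vs.ModelConfig(dilation_rates=(1, 2, 2, 4))
        with pytest.raises(InvalidConfigError):
            vs.ModelConfig(dilation_rates=(1, 2, 4))
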