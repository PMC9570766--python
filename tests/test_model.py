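"""Architecture contracts: shapes, attention blocks, parameter ordering."""

import numpy as np
import pytest

from pestseg.model import (SCSE, ModelConfig, ResNeStProjectedEncoder,
                           RsprUnetPP, SlimSplitAttnEncoder,
                           SplitAttentionBlock, SplitAttentionSpec,
                           adapt_pretrained_stem, load_checkpoint,
                           save_checkpoint)
from pestseg.nn import Tensor


def _x(rng, shape):
    return Tensor(rng.normal(size=shape).astype(np.float32))


# -------------------------------------------------------- split attention

class TestSplitAttention:
    def test_output_shape_stride1(self, rng):
        blk = SplitAttentionBlock(8, 8, SplitAttentionSpec(radix=2)).eval()
        out = blk(_x(rng, (2, 8, 6, 6)))
        assert out.shape == (2, 8, 6, 6)

    def test_radix1_uses_sigmoid_gate(self, rng):
        """radix=1 degenerates to an SE-gated residual block (weights in (0,1))."""
        blk = SplitAttentionBlock(4, 4, SplitAttentionSpec(radix=1)).eval()
        x = _x(rng, (1, 4, 5, 5))
        out = blk(x)
        assert out.shape == x.shape
        # a softmax over a single branch would force all weights to exactly 1;
        # sigmoid keeps them strictly inside (0, 1), so outputs must differ
        blk.probe_uniform_gate = True
        out_uniform = blk(x)
        assert not np.allclose(out.data, out_uniform.data)

    def test_uniform_gate_matches_loop_oracle(self, rng):
        """Forced-uniform gate: output == relu(mean branches + shortcut)."""
        spec = SplitAttentionSpec(radix=2, cardinality=1)
        blk = SplitAttentionBlock(2, 2, spec, rng=np.random.default_rng(0))
        blk.eval()
        blk.probe_uniform_gate = True
        x = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        got = blk(Tensor(x)).data

        # loop oracle: grouped 3x3 conv, identity eval-BN, relu, branch mean
        w = blk.conv.weight.data  # (4, 1, 3, 3), groups=2
        gamma = blk.bn.weight.data
        beta = blk.bn.bias.data
        rm, rv = blk.bn.running_mean, blk.bn.running_var
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        u = np.zeros((1, 4, 4, 4))
        for o in range(4):
            g = o // 2  # group index: 2 groups, one input channel each
            for i in range(4):
                for j in range(4):
                    acc = 0.0
                    for di in range(3):
                        for dj in range(3):
                            acc += w[o, 0, di, dj] * xp[0, g, i + di, j + dj]
                    u[0, o, i, j] = acc
        u = (u - rm.reshape(1, -1, 1, 1)) / np.sqrt(rv.reshape(1, -1, 1, 1)
                                                    + blk.bn.eps)
        u = np.maximum(gamma.reshape(1, -1, 1, 1) * u
                       + beta.reshape(1, -1, 1, 1), 0)
        fused = 0.5 * (u[:, :2] + u[:, 2:])
        want = np.maximum(fused + x, 0)
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_channel_divisibility_error(self):
        with pytest.raises(ValueError, match="divisible"):
            SplitAttentionBlock(3, 4, SplitAttentionSpec(radix=2))


# ------------------------------------------------------------------- scSE

class TestSCSE:
    def test_zero_input_zero_output(self, rng):
        for variant in ("scse", "cse", "sse"):
            blk = SCSE(4, variant=variant).eval()
            out = blk(Tensor(np.zeros((1, 4, 3, 3), dtype=np.float32)))
            np.testing.assert_array_equal(out.data, 0)

    def test_identity_variant_bit_for_bit(self, rng):
        x = _x(rng, (2, 4, 3, 3))
        out = SCSE(4, variant="none")(x)
        assert out is x

    def test_cse_gate_hand_computed(self):
        """2-channel constant input: gate follows the two linear layers."""
        blk = SCSE(2, reduction=2, variant="cse",
                   rng=np.random.default_rng(3)).eval()
        a, b = 0.7, -0.4
        x = np.zeros((1, 2, 4, 4), dtype=np.float32)
        x[0, 0], x[0, 1] = a, b
        got = blk(Tensor(x)).data
        w1 = blk.cse_fc1.weight.data.reshape(1, 2)
        b1 = blk.cse_fc1.bias.data
        w2 = blk.cse_fc2.weight.data.reshape(2, 1)
        b2 = blk.cse_fc2.bias.data
        hidden = max(w1 @ np.array([a, b]) + b1, np.zeros(1))
        gate = 1 / (1 + np.exp(-(w2 @ hidden + b2)))
        np.testing.assert_allclose(got[0, 0], a * gate[0], atol=1e-6)
        np.testing.assert_allclose(got[0, 1], b * gate[1], atol=1e-6)

    def test_scse_is_elementwise_max_of_parts(self, rng):
        blk = SCSE(4, variant="scse", rng=np.random.default_rng(1)).eval()
        x = _x(rng, (1, 4, 5, 5))
        cse = SCSE(4, variant="cse")
        cse.cse_fc1, cse.cse_fc2 = blk.cse_fc1, blk.cse_fc2
        sse = SCSE(4, variant="sse")
        sse.sse_conv = blk.sse_conv
        want = np.maximum(cse(x).data, sse(x).data)
        np.testing.assert_allclose(blk(x).data, want, atol=1e-7)


# ----------------------------------------------------------------- encoders

def test_slim_encoder_strides(rng):
    widths = (4, 8, 16, 32, 64)
    enc = SlimSplitAttnEncoder(6, widths, SplitAttentionSpec(),
                               np.random.default_rng(0))
    enc.eval()
    feats = enc(_x(rng, (1, 6, 64, 64)))
    assert [f.shape[1] for f in feats] == list(widths)
    assert [f.shape[2] for f in feats] == [32, 16, 8, 4, 2]


def test_projected_encoder_strides_and_projection(rng):
    widths = (4, 8, 16, 32, 64)
    enc = ResNeStProjectedEncoder(6, widths, SplitAttentionSpec(),
                                  np.random.default_rng(0), depths=(1, 1, 1, 1))
    enc.eval()
    feats = enc(_x(rng, (1, 6, 64, 64)))
    assert [f.shape[1] for f in feats] == list(widths)
    assert [f.shape[2] for f in feats] == [32, 16, 8, 4, 2]


class TestAdaptPretrainedStem:
    def test_identity_for_rgb(self, rng):
        w = rng.normal(size=(8, 3, 3, 3))
        np.testing.assert_array_equal(adapt_pretrained_stem(w, 3), w)

    def test_constant_input_preactivation_preserved(self, rng):
        """Linearity: the adapted stem responds to constants exactly like RGB."""
        from pestseg.nn import conv2d

        w3 = rng.normal(size=(8, 3, 3, 3)).astype(np.float64)
        w24 = adapt_pretrained_stem(w3, 24)
        assert w24.shape == (8, 24, 3, 3)
        c = 0.713
        x3 = Tensor(np.full((1, 3, 8, 8), c))
        x24 = Tensor(np.full((1, 24, 8, 8), c))
        out3 = conv2d(x3, Tensor(w3), padding=1).data
        out24 = conv2d(x24, Tensor(w24), padding=1).data
        np.testing.assert_allclose(out24, out3, atol=1e-10)

    def test_shape_validation(self, rng):
        with pytest.raises(ValueError, match="3"):
            adapt_pretrained_stem(rng.normal(size=(8, 4, 3, 3)), 24)


# -------------------------------------------------------------- full model

class TestRsprUnetPP:
    def test_forward_shape_default_widths(self, tiny_model, rng):
        out = tiny_model(_x(rng, (1, 4, 64, 64)))
        assert out["probs"].shape == (1, 3, 64, 64)
        assert len(out["heads"]) == 4
        for h in out["heads"]:
            assert h.shape == (1, 3, 64, 64)
            assert h.data.min() >= 0 and h.data.max() <= 1

    @pytest.mark.parametrize("widths", [(32, 64, 128, 256, 512),
                                        (64, 128, 256, 512, 1024)])
    def test_width_ablations_build_and_run(self, widths, rng):
        cfg = ModelConfig(in_channels=4, decoder_widths=widths)
        model = RsprUnetPP(cfg, seed=0).eval()
        out = model(_x(rng, (1, 4, 64, 64)))
        assert out["probs"].shape == (1, 3, 64, 64)

    def test_parameter_count_ordering(self):
        counts = {
            att: RsprUnetPP(ModelConfig(in_channels=4,
                                        decoder_widths=(4, 8, 16, 32, 64),
                                        attention=att), seed=0).num_parameters()
            for att in ("scse", "cse", "sse", "none")
        }
        assert counts["none"] < counts["sse"] < counts["scse"]
        assert counts["none"] < counts["cse"] < counts["scse"]

    def test_probe_gates_make_attention_variants_identical(self, rng):
        cfg_s = ModelConfig(in_channels=4, decoder_widths=(4, 8, 16, 32, 64),
                            attention="scse")
        cfg_n = ModelConfig(in_channels=4, decoder_widths=(4, 8, 16, 32, 64),
                            attention="none")
        m_s = RsprUnetPP(cfg_s, seed=0).eval()
        m_n = RsprUnetPP(cfg_n, seed=1).eval()
        shared = m_n.state_dict()
        full = m_s.state_dict()
        m_n.load_state_dict({k: full[k] for k in shared})
        m_s.set_probe_identity(True)
        x = _x(rng, (1, 4, 64, 64))
        np.testing.assert_allclose(m_s(x)["probs"].data, m_n(x)["probs"].data,
                                   atol=1e-7)

    def test_combine_last_equals_final_head(self, rng):
        cfg = ModelConfig(in_channels=4, decoder_widths=(4, 8, 16, 32, 64),
                          deep_supervision_combine="last")
        m = RsprUnetPP(cfg, seed=0).eval()
        out = m(_x(rng, (1, 4, 64, 64)))
        np.testing.assert_array_equal(out["probs"].data, out["heads"][-1].data)

    def test_input_validation(self, tiny_model, rng):
        with pytest.raises(ValueError, match="expects 4"):
            tiny_model(_x(rng, (1, 5, 64, 64)))
        with pytest.raises(ValueError, match="divisible by 32"):
            tiny_model(_x(rng, (1, 4, 60, 60)))

    def test_forward_backward_finite_gradients(self, rng):
        cfg = ModelConfig(in_channels=4, decoder_widths=(4, 8, 16, 32, 64))
        model = RsprUnetPP(cfg, seed=2)
        model.train()
        x = _x(rng, (2, 4, 32, 32))
        loss = (model(x)["probs"] ** 2).mean()
        loss.backward()
        for name, p in model.named_parameters().items():
            assert p.grad is not None, name
            assert np.isfinite(p.grad).all(), name

    def test_predict_argmax_and_determinism(self, tiny_model, rng):
        x = rng.normal(size=(1, 4, 64, 64)).astype(np.float32)
        a = tiny_model.predict(x)
        b = tiny_model.predict(x)
        np.testing.assert_array_equal(a, b)
        assert set(np.unique(a)) <= {0, 1, 2}

    def test_checkpoint_round_trip(self, tiny_model, tmp_path, rng):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, tiny_model, extra={"note": 1})
        model, extra = load_checkpoint(path)
        assert extra == {"note": 1}
        assert model.cfg == tiny_model.cfg
        x = rng.normal(size=(1, 4, 64, 64)).astype(np.float32)
        tiny_model.eval()
        np.testing.assert_array_equal(model.predict(x), tiny_model.predict(x))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            ModelConfig(decoder_widths=(16, 16, 32, 64, 128))
        with pytest.raises(ValueError, match="attention"):
            ModelConfig(attention="bogus")
        cfg = ModelConfig(in_channels=7, attention="cse",
                          head_activation="softmax")
        assert ModelConfig.from_json(cfg.to_json()) == cfg
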