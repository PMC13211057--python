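"""Architecture contracts: shape chain, parameter and FLOP accounting,
attention semantics, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegdecoder.model import (
    EEGNetConfig,
    ModelConfig,
    build_eegdecoder,
    build_eegnet,
    count_flops,
    count_parameters,
    count_parameters_closed_form,
    decoder_forward,
    expected_eegdecoder_parameters,
    forward_with_intermediates,
    scaled_dot_product_attention,
    temporal_mean_pool,
)


class TestShapeChain:
    def test_sequence_length_derivation(self):
        cfg = ModelConfig()
        # 1280 -(k25 valid)-> 1256 -(/4)-> 314 -(k15 valid)-> 300 -(/4)-> 75
        assert cfg.sequence_length == 75
        assert cfg.d_k == 32

    def test_cnn_output_is_64_by_75(self, rng):
        net = build_eegdecoder(seed=0)
        x = rng.standard_normal((2, 19, 1280)).astype(np.float32)
        _, inter = forward_with_intermediates(net, x)
        assert inter["conv1"].shape == (2, 64, 1256)
        assert inter["pool1"].shape == (2, 64, 314)
        assert inter["conv2"].shape == (2, 64, 300)
        assert inter["pool2"].shape == (2, 64, 75)
        assert inter["to_sequence"].shape == (2, 75, 64)
        assert inter["mean_pool"].shape == (2, 64)

    def test_forward_output_shape_and_finiteness(self, rng):
        net = build_eegdecoder(seed=0)
        out = decoder_forward(net, rng.standard_normal((8, 19, 1280)))
        assert out.shape == (8, 3)
        assert np.all(np.isfinite(out))

    def test_wrong_shape_rejected_with_expected_vs_got(self, rng):
        net = build_eegdecoder(seed=0)
        with pytest.raises(ValueError, match=r"\(N, 19, 1280\)"):
            decoder_forward(net, rng.standard_normal((2, 19, 1000)))

    def test_duplicated_trial_gives_identical_rows_in_eval(self, rng):
        net = build_eegdecoder(seed=0)
        x = rng.standard_normal((1, 19, 1280)).astype(np.float32)
        batch = np.concatenate([x, x, x])
        out = decoder_forward(net, batch)
        assert np.array_equal(out[0], out[1])
        assert np.array_equal(out[0], out[2])

    def test_batch_permutation_equivariance(self, rng):
        net = build_eegdecoder(seed=0)
        x = rng.standard_normal((6, 19, 1280)).astype(np.float32)
        perm = rng.permutation(6)
        assert np.allclose(decoder_forward(net, x)[perm],
                           decoder_forward(net, x[perm]), atol=1e-5)


class TestParameterCount:
    def test_enumeration_equals_closed_form(self):
        net = build_eegdecoder(seed=0)
        assert count_parameters(net) == count_parameters_closed_form(net)
        assert count_parameters(net) == expected_eegdecoder_parameters()

    def test_default_total_is_654723(self):
        assert count_parameters(build_eegdecoder(seed=0)) == 654_723

    def test_cnn_front_end_alone(self):
        # 19*64*25+64 + 2*64 + 64*64*15+64 + 2*64
        net = build_eegdecoder(seed=0)
        cnn = sum(l.param_count() for l in net.layers[:8])
        assert cnn == 19 * 64 * 25 + 64 + 128 + 64 * 64 * 15 + 64 + 128 == 92_224

    def test_classifier_head_alone(self):
        net = build_eegdecoder(seed=0)
        assert net.layers[-1].param_count() == 64 * 3 + 3 == 195
        assert count_parameters(net) - net.layers[-1].param_count() == 654_528

    def test_eegnet_separable_width(self):
        cfg = EEGNetConfig()
        assert cfg.f2 == cfg.f1 * cfg.depth_multiplier == 16
        net = build_eegnet(cfg, seed=0)
        assert count_parameters(net) == count_parameters_closed_form(net)


class TestFlops:
    def test_total_within_band(self):
        flops = count_flops(build_eegdecoder(seed=0))
        assert 189e6 <= flops <= 231e6  # ~2.1e8 under the MACx2 convention

    def test_conv1_macs_closed_form(self):
        net = build_eegdecoder(seed=0)
        conv1 = net.layers[0]
        flops, out_shape = conv1.flops((19, 1280))
        assert out_shape == (64, 1256)
        assert flops == 2 * (19 * 25 * 64 * 1256) + 64 * 1256

    def test_linear_head_flops(self):
        net = build_eegdecoder(seed=0)
        head = net.layers[-1]
        flops, _ = head.flops((64,))
        assert flops == 2 * 64 * 3 + 3

    def test_unknown_layer_kind_raises(self):
        class Mystery:
            name = "mystery"

        net = build_eegdecoder(seed=0)
        net.layers.insert(3, Mystery())
        with pytest.raises(Exception):
            count_flops(net)


class TestAttention:
    def test_single_timestep_returns_v(self, rng):
        q, k, v = (rng.standard_normal((1, 4)) for _ in range(3))
        assert np.allclose(scaled_dot_product_attention(q, k, v), v)

    def test_zero_scores_average_v(self, rng):
        t, d = 5, 4
        q = np.zeros((t, d))
        k = rng.standard_normal((t, d))
        v = rng.standard_normal((t, d))
        out = scaled_dot_product_attention(q, k, v)
        assert np.allclose(out, np.tile(v.mean(axis=0), (t, 1)))

    def test_matches_explicit_loop_oracle(self, rng):
        q = rng.standard_normal((5, 4))
        k = rng.standard_normal((5, 4))
        v = rng.standard_normal((5, 4))
        out = scaled_dot_product_attention(q, k, v)
        expected = np.zeros_like(out)
        for i in range(5):
            scores = np.array([q[i] @ k[j] / 2.0 for j in range(5)])  # sqrt(4)=2
            w = np.exp(scores - scores.max())
            w /= w.sum()
            expected[i] = sum(w[j] * v[j] for j in range(5))
        assert np.allclose(out, expected, atol=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 8), st.integers(1, 8))
    def test_rows_are_stochastic(self, seed, t, dk):
        r = np.random.default_rng(seed)
        q, k = r.standard_normal((2, t, dk))
        v = np.eye(t)  # attention weights appear directly in the output
        weights = scaled_dot_product_attention(q, k, v)
        assert np.allclose(weights.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(weights >= 0)

    def test_encoder_attention_rows_sum_to_one(self, rng):
        net = build_eegdecoder(seed=0)
        decoder_forward(net, rng.standard_normal((2, 19, 1280)))
        for lyr in net.layers:
            if hasattr(lyr, "attn"):
                a = lyr.attn.last_attention
                assert a.shape[-2:] == (75, 75)
                assert np.allclose(a.sum(axis=-1), 1.0, atol=1e-6)


class TestMeanPool:
    def test_identical_rows_return_the_row(self):
        v = np.arange(8.0)
        z = np.tile(v, (75, 1))
        assert np.allclose(temporal_mean_pool(z), v)

    def test_default_embedding_size(self, rng):
        assert temporal_mean_pool(rng.standard_normal((75, 64))).shape == (64,)

    def test_matches_summation_oracle(self, rng):
        z = rng.standard_normal((75, 64))
        manual = sum(z[t] for t in range(75)) / 75
        assert np.allclose(temporal_mean_pool(z), manual, atol=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            temporal_mean_pool(np.empty((0, 64)))


class TestEEGNet:
    def test_forward_contract(self, rng):
        net = build_eegnet(seed=0)
        out = net.forward(rng.standard_normal((4, 19, 1280)).astype(np.float32))
        assert out.shape == (4, 3)
        assert np.all(np.isfinite(out))

    def test_eval_forward_is_deterministic_despite_dropout(self, rng):
        net = build_eegnet(seed=0)
        x = rng.standard_normal((2, 19, 1280)).astype(np.float32)
        assert np.array_equal(net.forward(x), net.forward(x))

    def test_depthwise_maxnorm_constraint_enforced(self, rng):
        net = build_eegnet(seed=0)
        for p in net.parameters():
            if p.max_norm is not None and "depthwise" in p.name:
                p.data *= 100.0
                p.apply_constraint()
                norms = np.sqrt((p.data**2).sum(axis=p.max_norm_axes))
                assert np.all(norms <= p.max_norm + 1e-5)


class TestGradientFlow:
    def test_one_step_changes_every_parameter(self, rng):
        """After one optimization step on random data every trainable tensor
        must move (no dead branches)."""
        from eegdecoder.nn import Adam, softmax_cross_entropy

        cfg = ModelConfig(input_samples=320)
        net = build_eegdecoder(cfg, seed=1)
        x = rng.standard_normal((8, 19, 320)).astype(np.float32)
        y = np.array([0, 1, 2, 0, 1, 2, 0, 1])
        before = {p.name: p.data.copy() for p in net.parameters()}
        opt = Adam(net.parameters(), lr=1e-3)
        opt.zero_grad()
        _, grad = softmax_cross_entropy(net.forward(x, training=True), y)
        net.backward(grad)
        opt.step()
        for p in net.parameters():
            assert not np.array_equal(before[p.name], p.data), p.name
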