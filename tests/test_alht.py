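"""Hierarchical transformer components against closed-form and brute-force oracles."""

import numpy as np
import pytest

from osascreen.alht import (ClassifierHead, ContextualAggregate,
                            ConvNoiseSuppress, CrossModalRefine, EncoderStack,
                            FeatureProject, FrameWeighting, ModelConfig,
                            TemporalFocus, TokenDecoder, beam_search,
                            consistency_loss, cross_entropy, linguistic_loss,
                            positional_encode, positional_encoding,
                            total_loss)
from osascreen.autodiff import Tensor
from osascreen.nn import scaled_dot_attention


class TestFeatureProject:
    def test_identity_weights_pass_input_through(self, rng):
        proj = FeatureProject(4, 4, rng)
        proj.proj.weight.data = np.eye(4)
        proj.proj.bias.data = np.zeros(4)
        x = rng.normal(size=(5, 4))
        np.testing.assert_allclose(proj(x).data, x)

    def test_zero_weights_give_bias_rows(self, rng):
        proj = FeatureProject(3, 6, rng)
        proj.proj.weight.data = np.zeros((3, 6))
        proj.proj.bias.data = rng.normal(size=6)
        out = proj(rng.normal(size=(4, 3))).data
        np.testing.assert_allclose(out, np.broadcast_to(proj.proj.bias.data, (4, 6)))

    def test_matches_direct_affine_oracle(self, rng):
        proj = FeatureProject(5, 7, rng)
        x = rng.normal(size=(6, 5))
        expected = x @ proj.proj.weight.data + proj.proj.bias.data
        np.testing.assert_allclose(proj(x).data, expected, atol=1e-6)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            FeatureProject(5, 7, rng)(rng.normal(size=(6, 4)))


class TestPositionalEncoding:
    def test_position_zero_sines_are_zero(self):
        table = positional_encoding(4, 8)
        np.testing.assert_allclose(table[0, 0::2], 0.0)
        np.testing.assert_allclose(table[0, 1::2], 1.0)  # cos(0)

    def test_first_position_first_dimension_is_sin_one(self):
        table = positional_encoding(2, 8)
        assert abs(table[1, 0] - np.sin(1.0)) < 1e-12

    def test_encoding_is_content_independent(self, rng):
        a = rng.normal(size=(6, 8))
        b = rng.normal(size=(6, 8))
        np.testing.assert_allclose(positional_encode(a).data - a,
                                   positional_encode(b).data - b)

    def test_sine_only_mode_uses_sine_everywhere(self):
        table = positional_encoding(3, 4, mode="sine_only")
        np.testing.assert_allclose(table[0], 0.0)


class TestEncoderStack:
    def test_zero_layers_is_identity(self, rng):
        stack = EncoderStack(0, 8, 2, 16, 0.0, rng)
        x = Tensor(rng.normal(size=(5, 8)))
        np.testing.assert_array_equal(stack(x).data, x.data)

    @pytest.mark.parametrize("n_layers", [1, 3])
    def test_shape_preserved(self, rng, n_layers):
        stack = EncoderStack(n_layers, 8, 2, 16, 0.0, rng)
        assert stack(Tensor(rng.normal(size=(2, 5, 8)))).shape == (2, 5, 8)

    def test_deterministic_without_dropout(self, rng):
        stack = EncoderStack(2, 8, 2, 16, 0.2, rng)
        x = Tensor(rng.normal(size=(5, 8)))
        np.testing.assert_array_equal(stack(x, rng=None).data, stack(x, rng=None).data)


class TestConvNoiseSuppress:
    def test_identity_kernel_passes_through(self, rng):
        conv = ConvNoiseSuppress(4, width=3)
        x = Tensor(rng.normal(size=(6, 4)))
        np.testing.assert_allclose(conv(x).data, x.data)

    def test_averaging_kernel_on_constant_input(self):
        conv = ConvNoiseSuppress(2, width=3)
        conv.kernel.data = np.full((3, 2), 1 / 3)
        x = Tensor(np.ones((8, 2)) * 5.0)
        out = conv(x).data
        np.testing.assert_allclose(out[1:-1], 5.0)  # interior; edges zero-padded

    def test_matches_sliding_window_oracle(self, rng):
        conv = ConvNoiseSuppress(3, width=3)
        conv.kernel.data = rng.normal(size=(3, 3))
        x = rng.normal(size=(7, 3))
        padded = np.pad(x, ((1, 1), (0, 0)))
        expected = sum(padded[j:j + 7] * conv.kernel.data[j] for j in range(3))
        np.testing.assert_allclose(conv(Tensor(x)).data, expected, atol=1e-12)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            ConvNoiseSuppress(4, width=2)


class TestFrameWeighting:
    def _identity_projections(self, fw):
        for proj in (fw.proj_q, fw.proj_k, fw.proj_v):
            proj.weight.data = np.eye(proj.weight.data.shape[0])
            proj.bias.data[:] = 0.0

    def test_single_frame_gets_weight_one(self, rng):
        fw = FrameWeighting(3, rng)
        out, result = fw(Tensor(rng.normal(size=(1, 3))))
        np.testing.assert_allclose(result.weights, [[1.0]])

    def test_identical_frames_get_uniform_weights(self, rng):
        fw = FrameWeighting(4, rng)
        x = Tensor(np.tile(rng.normal(size=(1, 4)), (5, 1)))
        _, result = fw(x)
        np.testing.assert_allclose(result.weights, 1 / 5, atol=1e-12)

    def test_scaled_dot_attention_matches_softmax_oracle(self):
        """Q=[[1],[0]], K=[[1],[0]], V=[[2],[4]]: first output 0.7311*2+0.2689*4."""
        q = Tensor(np.array([[1.0], [0.0]]))
        k = Tensor(np.array([[1.0], [0.0]]))
        v = Tensor(np.array([[2.0], [4.0]]))
        out, weights = scaled_dot_attention(q, k, v)
        e = np.exp(1.0)
        w00 = e / (e + 1.0)
        assert abs(w00 - 0.7311) < 1e-4
        np.testing.assert_allclose(out.data[0, 0], w00 * 2 + (1 - w00) * 4, atol=1e-9)
        assert abs(out.data[0, 0] - 2.5378) < 1e-3

    def test_weights_row_stochastic(self, rng):
        fw = FrameWeighting(4, rng)
        _, result = fw(Tensor(rng.normal(size=(6, 4)) * 3))
        np.testing.assert_allclose(result.weights.sum(axis=-1), 1.0, atol=1e-9)


class TestTemporalFocus:
    def test_single_token_single_frame_returns_projected_value(self, rng):
        focus = TemporalFocus(3, rng)
        acoustic = Tensor(rng.normal(size=(1, 3)))
        _, c_focus = focus(Tensor(rng.normal(size=(1, 3))), acoustic)
        np.testing.assert_allclose(c_focus.data, focus.proj_v(acoustic).data, atol=1e-12)

    def test_identical_frames_make_weights_irrelevant(self, rng):
        focus = TemporalFocus(4, rng)
        frame = rng.normal(size=(1, 4))
        acoustic = Tensor(np.tile(frame, (7, 1)))
        _, c_focus = focus(Tensor(rng.normal(size=(3, 4))), acoustic)
        expected = focus.proj_v(Tensor(frame)).data
        np.testing.assert_allclose(c_focus.data, np.tile(expected, (3, 1)), atol=1e-9)

    def test_two_by_two_matches_direct_formula(self, rng):
        focus = TemporalFocus(2, rng)
        tokens, acoustic = rng.normal(size=(2, 2)), rng.normal(size=(2, 2))
        result, c_focus = focus(Tensor(tokens), Tensor(acoustic))
        q = tokens @ focus.proj_q.weight.data + focus.proj_q.bias.data
        k = acoustic @ focus.proj_k.weight.data + focus.proj_k.bias.data
        v = acoustic @ focus.proj_v.weight.data + focus.proj_v.bias.data
        scores = q @ k.T / np.sqrt(2)
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(result.weights, w, atol=1e-6)
        np.testing.assert_allclose(c_focus.data, w @ v, atol=1e-6)


class TestContextualAggregate:
    def test_zero_scalars_reduce_to_layernorm_of_focus(self, rng):
        agg = ContextualAggregate(4, 8, rng)
        agg.alpha.data = np.array(0.0)
        agg.beta.data = np.array(0.0)
        c_focus = Tensor(rng.normal(size=(3, 4)))
        c_agg, _ = agg(c_focus, Tensor(rng.normal(size=4)), Tensor(rng.normal(size=4)))
        from osascreen.autodiff import layer_norm
        np.testing.assert_allclose(c_agg.data,
                                   layer_norm(c_focus, agg.norm.gain, agg.norm.bias).data)

    def test_rows_have_zero_mean_pre_affine(self, rng):
        agg = ContextualAggregate(6, 8, rng)
        agg.norm.gain.data[:] = 1.0
        agg.norm.bias.data[:] = 0.0
        c_agg, _ = agg(Tensor(rng.normal(size=(4, 6))), Tensor(rng.normal(size=6)),
                       Tensor(rng.normal(size=6)))
        np.testing.assert_allclose(c_agg.data.mean(axis=-1), 0.0, atol=1e-5)

    def test_zero_ffn_weights_make_final_equal_agg(self, rng):
        agg = ContextualAggregate(4, 8, rng)
        agg.ffn.fc1.weight.data[:] = 0.0
        agg.ffn.fc1.bias.data[:] = 0.0
        agg.ffn.fc2.weight.data[:] = 0.0
        agg.ffn.fc2.bias.data[:] = 0.0
        c_agg, c_final = agg(Tensor(rng.normal(size=(3, 4))),
                             Tensor(rng.normal(size=4)), Tensor(rng.normal(size=4)))
        np.testing.assert_allclose(c_final.data, c_agg.data)


class TestCrossModalRefine:
    def test_zero_predictions_with_zero_bias_give_uniform_rows(self, rng):
        refine = CrossModalRefine(4, rng)
        refine.proj_q.bias.data[:] = 0.0
        result = refine(Tensor(np.zeros((3, 4))), Tensor(rng.normal(size=(5, 4))))
        np.testing.assert_allclose(result.weights, 1 / 5, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        refine = CrossModalRefine(4, rng)
        result = refine(Tensor(rng.normal(size=(3, 4)) * 4),
                        Tensor(rng.normal(size=(6, 4))))
        np.testing.assert_allclose(result.weights.sum(axis=-1), 1.0, atol=1e-6)

    def test_matches_direct_oracle(self, rng):
        refine = CrossModalRefine(3, rng)
        y_pred, k_focus = rng.normal(size=(2, 3)), rng.normal(size=(4, 3))
        result = refine(Tensor(y_pred), Tensor(k_focus))
        q = y_pred @ refine.proj_q.weight.data + refine.proj_q.bias.data
        scores = q @ k_focus.T / np.sqrt(3)
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(result.weights, w, atol=1e-8)


def _tiny_decoder(rng, n_layers=1, d_model=8):
    config = ModelConfig.tiny(n_decoder_layers=n_layers, d_model=d_model,
                              d_ffn=16, dropout=0.0)
    return TokenDecoder(config, rng)


class TestDecoding:
    def test_zero_output_matrix_gives_uniform_distribution(self, rng):
        dec = _tiny_decoder(rng)
        dec.w_out.weight.data[:] = 0.0
        dec.w_out.bias.data[:] = 0.0
        memory = Tensor(rng.normal(size=(4, 8)))
        probs = dec.decode_step([], memory).data
        np.testing.assert_allclose(probs, 1 / 3, atol=1e-12)

    def test_distribution_sums_to_one(self, rng):
        dec = _tiny_decoder(rng, n_layers=2)
        memory = Tensor(rng.normal(size=(5, 8)))
        for prefix in ([], [0], [1, 2]):
            assert abs(dec.decode_step(prefix, memory).data.sum() - 1.0) < 1e-6

    def test_argmax_matches_logit_oracle(self, rng):
        dec = _tiny_decoder(rng)
        memory = Tensor(rng.normal(size=(4, 8)))
        states = dec._states([1], memory)
        logits = states.data[-1] @ dec.w_out.weight.data + dec.w_out.bias.data
        probs = dec.decode_step([1], memory).data
        assert probs.argmax() == logits.argmax()


class TestBeamSearch:
    def test_width_one_equals_greedy_on_random_tiny_models(self):
        for trial in range(100):
            rng = np.random.default_rng(trial)
            dec = _tiny_decoder(rng)
            memory = Tensor(rng.normal(size=(3, 8)))
            beam = beam_search(dec, memory, width=1, max_len=3)
            greedy = []
            for _ in range(3):
                probs = dec.decode_step(greedy, memory).data
                greedy.append(int(probs.argmax()))
            assert beam == greedy

    def test_wide_beam_reproduces_exhaustive_argmax(self, rng):
        dec = _tiny_decoder(rng)
        memory = Tensor(rng.normal(size=(3, 8)))
        max_len, vocab = 4, 3
        best_seq, best_lp = None, -np.inf
        import itertools
        for seq in itertools.product(range(vocab), repeat=max_len):
            lp = 0.0
            for i in range(max_len):
                lp += float(np.log(dec.decode_step(list(seq[:i]), memory).data[seq[i]]))
            if lp > best_lp or (lp == best_lp and list(seq) < best_seq):
                best_seq, best_lp = list(seq), lp
        assert beam_search(dec, memory, width=vocab**max_len, max_len=max_len) == best_seq

    def test_ties_break_lexicographically(self, rng):
        class UniformModel:
            def decode_step(self, prefix, memory):
                return Tensor(np.full(3, 1 / 3))
        assert beam_search(UniformModel(), None, width=2, max_len=2) == [0, 0]

    def test_zero_width_rejected(self, rng):
        with pytest.raises(ValueError):
            beam_search(_tiny_decoder(rng), Tensor(np.zeros((2, 8))), width=0, max_len=2)


class TestClassifierHead:
    def test_zero_logits_give_half_confidence(self, rng):
        head = ClassifierHead(4, rng)
        head.proj.weight.data[:] = 0.0
        head.proj.bias.data[:] = 0.0
        _, conf = head.classify(Tensor(rng.normal(size=(3, 5, 4))))
        np.testing.assert_allclose(conf, 0.5)

    def test_confidence_bounded_by_half_and_one(self, rng):
        head = ClassifierHead(4, rng)
        _, conf = head.classify(Tensor(rng.normal(size=(10, 5, 4)) * 3))
        assert ((conf >= 0.5) & (conf <= 1.0)).all()

    def test_matches_pool_affine_softmax_oracle(self, rng):
        head = ClassifierHead(3, rng)
        x = rng.normal(size=(4, 6, 3))
        pooled = x.mean(axis=1)
        logits = pooled @ head.proj.weight.data + head.proj.bias.data
        expected = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(head(Tensor(x)).data, expected, atol=1e-9)


class TestLosses:
    def test_perfect_one_hot_predictions_give_zero(self):
        probs = Tensor(np.eye(3)[[0, 1, 2]])
        assert linguistic_loss(probs, [0, 1, 2]).item() < 1e-10

    def test_uniform_binary_gives_ln_two(self):
        probs = Tensor(np.full((4, 2), 0.5))
        assert abs(linguistic_loss(probs, [0, 1, 0, 1]).item() - np.log(2)) < 1e-12

    def test_matches_negative_log_sum_oracle(self, rng):
        raw = rng.random(size=(5, 3)) + 0.1
        probs = raw / raw.sum(axis=1, keepdims=True)
        targets = rng.integers(0, 3, size=5)
        expected = -np.mean(np.log(probs[np.arange(5), targets]))
        assert abs(linguistic_loss(Tensor(probs), targets).item() - expected) < 1e-12

    def test_zero_probability_clamped_with_warning(self):
        probs = Tensor(np.array([[1.0, 0.0]]))
        with pytest.warns(UserWarning):
            loss = cross_entropy(probs, np.array([1]))
        assert np.isfinite(loss.item())

    def test_consistency_identical_pooled_vectors_zero(self, rng):
        x = rng.normal(size=(4, 3))
        assert consistency_loss(Tensor(x), Tensor(x.copy())).item() == 0.0

    def test_consistency_hand_case(self):
        a = Tensor(np.array([[1.0, 2.0]]))
        b = Tensor(np.array([[0.0, 0.0]]))
        assert abs(consistency_loss(a, b).item() - 5.0) < 1e-12

    def test_consistency_quadratic_homogeneity(self, rng):
        a, b = rng.normal(size=(3, 4)), rng.normal(size=(5, 4))
        base = consistency_loss(Tensor(a), Tensor(b)).item()
        scaled = consistency_loss(Tensor(3 * a), Tensor(3 * b)).item()
        assert abs(scaled - 9 * base) < 1e-9

    def test_total_loss_algebra(self):
        breakdown = total_loss(Tensor(0.3), Tensor(0.2), 1.0, 1.0)
        assert abs(breakdown.value() - 0.5) < 1e-12
        assert abs(total_loss(Tensor(0.3), Tensor(0.2), 1.0, 0.0).value() - 0.3) < 1e-12
        assert abs(total_loss(Tensor(0.3), Tensor(0.2), 0.0, 2.0).value() - 0.4) < 1e-12
        with pytest.raises(ValueError):
            total_loss(Tensor(0.3), Tensor(0.2), -1.0, 0.0)
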