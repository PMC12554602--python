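"""Encoders: attention oracle, shape/determinism contracts, contrastive loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncofuse import (
    ClinicalEncoder,
    EncoderConfig,
    GenomicEncoder,
    ImageEncoder,
    contrastive_alignment_loss,
    scaled_dot_attention,
)
from oncofuse._autodiff import Tensor


def brute_force_attention(Q, K, V, d_k):
    """Independent nested-loop evaluation of softmax(QK^T/sqrt(d_k))V."""
    n_q, n_k = Q.shape[0], K.shape[0]
    out = np.zeros((n_q, V.shape[1]))
    for i in range(n_q):
        scores = np.array([Q[i] @ K[j] / np.sqrt(d_k) for j in range(n_k)])
        w = np.exp(scores - scores.max())
        w = w / w.sum()
        for j in range(n_k):
            out[i] += w[j] * V[j]
    return out


class TestScaledDotAttention:
    def test_single_token_returns_v_row(self):
        Q = np.array([[1.0, 2.0]])
        K = np.array([[0.3, -0.5]])
        V = np.array([[7.0, 8.0, 9.0]])
        np.testing.assert_allclose(scaled_dot_attention(Q, K, V, 2), V, atol=1e-12)

    def test_zero_scores_average_v_rows(self):
        Q = np.zeros((3, 2))
        K = np.ones((3, 2))
        V = np.arange(9.0).reshape(3, 3)
        out = scaled_dot_attention(Q, K, V, 2)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (3, 1)), atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = int(rng.integers(2, 7))
        Q, K = rng.normal(size=(t, 2)), rng.normal(size=(t, 2))
        V = rng.normal(size=(t, 3))
        np.testing.assert_allclose(
            scaled_dot_attention(Q, K, V, 2), brute_force_attention(Q, K, V, 2),
            atol=1e-6,
        )

    def test_attention_rows_are_convex_weights(self):
        rng = np.random.default_rng(0)
        Q, K, V = (rng.normal(size=(5, 4)) for _ in range(3))
        out = scaled_dot_attention(Q, K, V)
        # outputs lie within the coordinate-wise range of V rows
        assert (out <= V.max(axis=0) + 1e-12).all()
        assert (out >= V.min(axis=0) - 1e-12).all()

    def test_rejects_nonfinite_and_bad_dk(self):
        with pytest.raises(ValueError, match="non-finite"):
            scaled_dot_attention(np.array([[np.nan]]), np.ones((1, 1)), np.ones((1, 1)))
        with pytest.raises(ValueError, match="d_k"):
            scaled_dot_attention(np.ones((1, 1)), np.ones((1, 1)), np.ones((1, 1)), 0)


class TestImageEncoder:
    def test_output_shape_and_determinism(self):
        cfg = EncoderConfig()
        rng = np.random.default_rng(0)
        enc = ImageEncoder((8, 8, 1), cfg, np.random.default_rng(3))
        x = Tensor(rng.normal(size=(4, 8, 8, 1)))
        a, b = enc(x).data, enc(x).data
        assert a.shape == (4, cfg.shared_dim)
        assert np.isfinite(a).all()
        np.testing.assert_array_equal(a, b)

    def test_zero_input_zero_biases_gives_zero_embedding(self):
        enc = ImageEncoder((8, 8, 1), EncoderConfig(), np.random.default_rng(0))
        for conv in enc.convs:
            conv.bias.data[:] = 0.0
        enc.head.bias.data[:] = 0.0
        out = enc(Tensor(np.zeros((2, 8, 8, 1)))).data
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_shape_mismatch_names_shapes(self):
        enc = ImageEncoder((8, 8, 1), EncoderConfig(), np.random.default_rng(0))
        with pytest.raises(ValueError, match=r"\(8, 8, 1\)"):
            enc(Tensor(np.zeros((1, 6, 6, 1))))


class TestGenomicEncoder:
    def test_shape_determinism_and_finite(self):
        cfg = EncoderConfig()
        enc = GenomicEncoder(12, cfg, np.random.default_rng(1))
        tokens = np.random.default_rng(0).integers(0, 12, size=(3, 16))
        a, b = enc(tokens).data, enc(tokens).data
        assert a.shape == (3, cfg.shared_dim) and np.isfinite(a).all()
        np.testing.assert_array_equal(a, b)

    def test_out_of_vocab_token_reports_position(self):
        enc = GenomicEncoder(12, EncoderConfig(), np.random.default_rng(1))
        tokens = np.zeros((1, 16), dtype=int)
        tokens[0, 5] = 99
        with pytest.raises(ValueError, match=r"position.*5"):
            enc(tokens)

    def test_permutation_sensitivity_follows_positional_encoding(self):
        rng = np.random.default_rng(2)
        tokens = rng.integers(0, 12, size=(1, 16))
        perm = rng.permutation(16)
        with_pe = GenomicEncoder(12, EncoderConfig(positional_encoding=True),
                                 np.random.default_rng(4))
        without_pe = GenomicEncoder(12, EncoderConfig(positional_encoding=False),
                                    np.random.default_rng(4))
        assert not np.allclose(with_pe(tokens).data, with_pe(tokens[:, perm]).data)
        np.testing.assert_allclose(without_pe(tokens).data,
                                   without_pe(tokens[:, perm]).data, atol=1e-10)

    def test_single_token_pooling_is_identity(self):
        # mean pooling over one token equals that token's transformed vector:
        # the mean- and first-token-pooled encoders coincide
        mean_enc = GenomicEncoder(12, EncoderConfig(pooling="mean"),
                                  np.random.default_rng(5))
        first_enc = GenomicEncoder(12, EncoderConfig(pooling="first"),
                                   np.random.default_rng(5))
        tokens = np.array([[3]])
        np.testing.assert_allclose(mean_enc(tokens).data, first_enc(tokens).data,
                                   atol=1e-12)


class TestClinicalEncoder:
    def test_zero_input_zero_bias_relu_gives_zero(self):
        enc = ClinicalEncoder(8, EncoderConfig(activation="relu"),
                              np.random.default_rng(0))
        for layer in enc.layers:
            layer.bias.data[:] = 0.0
        enc.head.bias.data[:] = 0.0
        out = enc(Tensor(np.zeros((3, 8)))).data
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_no_hidden_layer_is_exact_affine_map(self):
        enc = ClinicalEncoder(4, EncoderConfig(hidden_widths=()),
                              np.random.default_rng(1))
        c = np.random.default_rng(2).normal(size=(1, 4))
        expected = c @ enc.head.weight.data + enc.head.bias.data
        np.testing.assert_allclose(enc(Tensor(c)).data, expected, atol=1e-14)

    def test_deterministic_without_dropout(self):
        enc = ClinicalEncoder(8, EncoderConfig(dropout_rate=0.0),
                              np.random.default_rng(1))
        x = Tensor(np.random.default_rng(0).normal(size=(2, 8)))
        np.testing.assert_array_equal(enc(x, train=True).data, enc(x).data)

    def test_wrong_length_raises(self):
        enc = ClinicalEncoder(8, EncoderConfig(), np.random.default_rng(1))
        with pytest.raises(ValueError, match="length"):
            enc(Tensor(np.zeros((1, 5))))


class TestContrastiveLoss:
    def test_satisfied_margin_gives_zero(self):
        a = np.zeros(4)
        neg = np.full(4, 1.0)  # squared distance 4 >= margin
        assert contrastive_alignment_loss(a, a, neg, margin=1.0) == 0.0

    def test_hand_evaluated_value(self):
        # margin 1, d(a,pos)^2 = 0.5, d(a,neg)^2 = 0.2 -> 1 + 0.5 - 0.2 = 1.3
        a = np.zeros(1)
        pos = np.array([np.sqrt(0.5)])
        neg = np.array([np.sqrt(0.2)])
        assert contrastive_alignment_loss(a, pos, neg, 1.0) == pytest.approx(1.3)

    def test_zero_margin_identical_pos_neg_cancels_in_both_modes(self):
        a, z = np.array([1.0, 2.0]), np.array([0.5, -1.0])
        assert contrastive_alignment_loss(a, z, z, 0.0) == 0.0
        assert contrastive_alignment_loss(a, z, z, 0.0, literal=True) == 0.0

    def test_literal_mode_swaps_distance_roles(self):
        a = np.zeros(1)
        pos, neg = np.array([1.0]), np.array([2.0])
        default = contrastive_alignment_loss(a, pos, neg, 1.0)      # 1 + 1 - 4 -> 0
        literal = contrastive_alignment_loss(a, pos, neg, 1.0, literal=True)  # 1+4-1=4
        assert default == 0.0
        assert literal == pytest.approx(4.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    def test_nonnegative_and_monotone_in_margin(self, seed, tau1, tau2):
        rng = np.random.default_rng(seed)
        a, pos, neg = (rng.normal(size=3) for _ in range(3))
        lo, hi = sorted((tau1, tau2))
        l_lo = contrastive_alignment_loss(a, pos, neg, lo)
        l_hi = contrastive_alignment_loss(a, pos, neg, hi)
        assert l_lo >= 0.0
        assert l_hi >= l_lo - 1e-12

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            contrastive_alignment_loss(np.zeros(2), np.zeros(3), np.zeros(2), 1.0)
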