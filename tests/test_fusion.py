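"""Fusion ops, objective, modality dropout and end-to-end training."""

import numpy as np
import pytest

from oncofuse import (
    CohortConfig,
    FusionParams,
    ModalityEmbedding,
    MultimodalFusionClassifier,
    classify,
    fuse,
    generate_cohort,
    modality_attention,
    modality_dropout,
    training_loss,
)
from oncofuse.fusion import _mask_dropout


def embeddings_from(vectors, present=None):
    present = present or [True] * len(vectors)
    mods = ["image", "genomic", "clinical"]
    return [ModalityEmbedding(np.asarray(v, float), mods[i % 3], present=present[i])
            for i, v in enumerate(vectors)]


class TestModalityAttention:
    def test_zero_scoring_vector_gives_uniform_weights(self):
        embs = embeddings_from([[1, 0], [0, 1], [2, 2]])
        alpha, _ = modality_attention(embs, np.zeros(2))
        np.testing.assert_allclose(alpha, 1 / 3, atol=1e-12)

    def test_hand_softmax_of_log2_and_zero(self):
        # e = (ln 2, 0) -> alpha = (2/3, 1/3)
        embs = embeddings_from([[np.log(2.0)], [0.0]])
        alpha, e = modality_attention(embs, np.array([1.0]))
        np.testing.assert_allclose(alpha, [2 / 3, 1 / 3], atol=1e-12)
        np.testing.assert_allclose(e, [np.log(2.0), 0.0])

    def test_absent_modality_gets_exactly_zero(self):
        embs = embeddings_from([[1], [1], [1]], present=[True, True, False])
        alpha, e = modality_attention(embs, np.zeros(1))
        np.testing.assert_allclose(alpha, [0.5, 0.5, 0.0], atol=1e-12)
        assert e[2] == -np.inf

    def test_no_present_modality_raises(self):
        embs = embeddings_from([[1]], present=[False])
        with pytest.raises(ValueError, match="present"):
            modality_attention(embs, np.zeros(1))

    def test_convexity_over_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            k = int(rng.integers(1, 4))
            present = [True] * k + [False] * (3 - k)
            rng.shuffle(present)
            embs = embeddings_from(rng.normal(size=(3, 4)) * 5, present=present)
            alpha, _ = modality_attention(embs, rng.normal(size=4))
            assert (alpha >= 0).all()
            assert abs(alpha.sum() - 1.0) <= 1e-9
            assert alpha[~np.array(present)].sum() == 0.0


class TestFuse:
    def test_selection_weight_returns_first_embedding(self):
        embs = embeddings_from([[1, 2], [3, 4], [5, 6]])
        np.testing.assert_array_equal(fuse(embs, [1, 0, 0]), [1, 2])

    def test_identical_embeddings_are_fixed_point(self):
        embs = embeddings_from([[2, 5]] * 3)
        np.testing.assert_allclose(fuse(embs, [0.2, 0.3, 0.5]), [2, 5], atol=1e-12)

    def test_hand_arithmetic(self):
        embs = embeddings_from([[1, 0], [0, 1]])
        np.testing.assert_allclose(fuse(embs, [0.25, 0.75]), [0.25, 0.75])

    def test_convex_hull_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            vecs = rng.normal(size=(3, 4))
            w = rng.dirichlet(np.ones(3))
            z = fuse(embeddings_from(vecs), w)
            assert (z <= vecs.max(axis=0) + 1e-12).all()
            assert (z >= vecs.min(axis=0) - 1e-12).all()

    def test_dimension_mismatch_raises(self):
        embs = embeddings_from([[1, 2], [1, 2, 3]])
        with pytest.raises(ValueError, match="dimension"):
            fuse(embs, [0.5, 0.5])


class TestClassify:
    def params(self, k=4, d=2, lam=0.0, beta=0.0):
        return FusionParams(w=np.zeros(d), w_out=np.zeros((k, d)),
                            b_out=np.zeros(k), lam=lam, beta=beta)

    def test_zero_head_gives_uniform_probabilities(self):
        _, probs = classify(np.ones(2), self.params(k=4))
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_hand_softmax_of_log_odds(self):
        p = FusionParams(w=np.zeros(1), w_out=np.array([[1.0], [1.0]]),
                         b_out=np.array([np.log(1.0), np.log(3.0)]))
        _, probs = classify(np.zeros(1), p)
        np.testing.assert_allclose(probs, [0.25, 0.75], atol=1e-12)

    def test_softmax_shift_invariance(self):
        p = self.params(k=3, d=2)
        p.b_out = np.array([0.1, 0.2, 0.3])
        _, base = classify(np.zeros(2), p)
        p.b_out = p.b_out + 100.0
        _, shifted = classify(np.zeros(2), p)
        np.testing.assert_allclose(base, shifted, atol=1e-12)


class TestTrainingLoss:
    def test_one_hot_correct_prediction_gives_zero(self):
        p = FusionParams(np.zeros(2), np.zeros((3, 2)), np.zeros(3))
        y_hat = np.array([0.0, 1.0, 0.0])
        assert training_loss(y_hat, 1, p) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_is_log_k(self):
        p = FusionParams(np.zeros(2), np.zeros((4, 2)), np.zeros(4))
        assert training_loss(np.full(4, 0.25), 2, p) == pytest.approx(np.log(4))

    def test_attention_penalty_hand_value(self):
        p = FusionParams(np.array([3.0, 4.0]), np.zeros((2, 2)), np.zeros(2), lam=1.0)
        loss = training_loss(np.array([0.0, 1.0]), 1, p)
        assert loss == pytest.approx(25.0, abs=1e-9)

    def test_aux_losses_weighted_sum(self):
        p = FusionParams(np.zeros(1), np.zeros((2, 1)), np.zeros(2))
        loss = training_loss(np.array([0, 1.0]), 1, p,
                             aux_losses={"contrastive": 2.0, "calibration": 1.0},
                             loss_weights={"contrastive": 0.1, "calibration": 0.5})
        assert loss == pytest.approx(0.7)

    def test_zero_probability_is_clipped_not_infinite(self):
        p = FusionParams(np.zeros(1), np.zeros((2, 1)), np.zeros(2))
        loss = training_loss(np.array([1.0, 0.0]), 1, p)
        assert np.isfinite(loss) and loss > 0

    def test_negative_regularizer_rejected(self):
        with pytest.raises(ValueError):
            FusionParams(np.zeros(1), np.zeros((2, 1)), np.zeros(2), lam=-1.0)


class TestModalityDropout:
    def test_rate_zero_is_identity(self):
        embs = embeddings_from(np.eye(3))
        out = modality_dropout(embs, 0.0, seed=0)
        assert [e.present for e in out] == [True, True, True]

    def test_single_present_modality_always_retained(self):
        embs = embeddings_from(np.eye(3), present=[False, True, False])
        for seed in range(30):
            out = modality_dropout(embs, 0.9, seed=seed)
            assert out[1].present

    def test_rate_one_rejected(self):
        with pytest.raises(ValueError):
            modality_dropout(embeddings_from(np.eye(3)), 1.0, seed=0)

    def test_drop_frequency_matches_binomial(self):
        rng = np.random.default_rng(0)
        mask = np.ones((10_000, 3), dtype=bool)
        out = _mask_dropout(mask, 0.5, rng)
        dropped = 1.0 - out.mean()
        se = np.sqrt(0.5 * 0.5 / 30_000)
        # restoration inflates retention by rate^3/3 ~ 0.042; allow for it
        assert abs(dropped - (0.5 - 0.5 ** 3 / 3)) < 3 * se
        assert out.any(axis=1).all()


class TestTraining:
    def test_single_epoch_contract(self):
        cohort = generate_cohort(CohortConfig(n_patients=10, seed=0))
        clf = MultimodalFusionClassifier(n_epochs=1, batch_size=8, vocab_size=12,
                                         random_state=0).fit(cohort)
        assert len(clf.history_) == 1
        assert np.isfinite(clf.history_[0]["loss"])

    def test_learns_linearly_separable_clinical_signal(self):
        cohort = generate_cohort(CohortConfig(
            n_patients=200, n_classes=2, informativeness=(0.0, 0.0, 1.0), seed=3))
        # separability oracle: plain logistic fit on the raw clinical features
        from sklearn.linear_model import LogisticRegression
        X = np.stack([s.clinical for s in cohort])
        y = np.array([s.label for s in cohort])
        assert LogisticRegression(max_iter=1000).fit(X, y).score(X, y) > 0.9
        clf = MultimodalFusionClassifier(n_epochs=20, batch_size=32,
                                         learning_rate=2e-3, vocab_size=12,
                                         random_state=0).fit(cohort)
        assert clf.score(cohort) > 0.9

    def test_identical_seeds_give_identical_parameters(self):
        cohort = generate_cohort(CohortConfig(n_patients=40, seed=1))
        fit = lambda: MultimodalFusionClassifier(
            n_epochs=3, batch_size=16, vocab_size=12, random_state=5).fit(cohort)
        s1, s2 = fit().net_.state_dict(), fit().net_.state_dict()
        assert s1.keys() == s2.keys()
        for key in s1:
            np.testing.assert_array_equal(s1[key], s2[key])

    def test_probabilities_and_prediction_contract(self):
        cohort = generate_cohort(CohortConfig(n_patients=30, n_classes=3, seed=2))
        clf = MultimodalFusionClassifier(n_epochs=2, vocab_size=12,
                                         random_state=0).fit(cohort)
        probs = clf.predict_proba(cohort)
        assert probs.shape == (30, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert set(clf.predict(cohort)) <= set(clf.classes_)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        clf = MultimodalFusionClassifier(n_epochs=3, weight_da=0.2)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()
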