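"""MC-dropout estimates, inverse-variance weighting, entropies, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncofuse import (
    CohortConfig,
    MultimodalFusionClassifier,
    attention_entropy,
    calibration_loss,
    generate_cohort,
    inverse_variance_weights,
    mc_dropout_predict,
    modality_variance,
    prediction_entropy,
    uncertainty_weighted_fuse,
)
from oncofuse.fusion import ModalityEmbedding


class TestMCDropout:
    def test_zero_dropout_rate_matches_deterministic_pass(self, clinical_cohort):
        clf = MultimodalFusionClassifier(
            n_epochs=2, vocab_size=12, fusion_dropout=0.0,
            encoder_config=None, random_state=0)
        # remove the clinical-encoder dropout site too
        from oncofuse.encoders import EncoderConfig
        clf.encoder_config = EncoderConfig(dropout_rate=0.0)
        clf.fit(clinical_cohort[:30])
        est = mc_dropout_predict(clf, clinical_cohort[:5], T=7, seed=3)
        np.testing.assert_allclose(est.per_class_variance, 0.0, atol=1e-18)
        np.testing.assert_allclose(
            est.mean, clf.predict_proba(clinical_cohort[:5]), atol=1e-12)

    def test_single_pass_has_zero_variance(self, trained_clf, clinical_cohort):
        est = mc_dropout_predict(trained_clf, clinical_cohort[:3], T=1, seed=0)
        np.testing.assert_array_equal(est.per_class_variance, 0.0)

    def test_seeded_estimates_are_bit_identical(self, trained_clf, clinical_cohort):
        a = mc_dropout_predict(trained_clf, clinical_cohort[0], T=20, seed=9)
        b = mc_dropout_predict(trained_clf, clinical_cohort[0], T=20, seed=9)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.per_class_variance, b.per_class_variance)
        assert a.entropy == b.entropy

    def test_mean_is_probability_vector_variance_nonnegative(
            self, trained_clf, clinical_cohort):
        est = mc_dropout_predict(trained_clf, clinical_cohort[:8], T=10, seed=1)
        np.testing.assert_allclose(est.mean.sum(axis=1), 1.0, atol=1e-9)
        assert (est.per_class_variance >= 0).all()

    def test_invalid_passes_rejected(self, trained_clf, clinical_cohort):
        with pytest.raises(ValueError, match="T"):
            mc_dropout_predict(trained_clf, clinical_cohort[0], T=0)


class TestModalityVariance:
    def test_seeded_runs_identical(self, trained_clf, clinical_cohort):
        a = modality_variance(trained_clf, clinical_cohort[0], T=5, seed=2)
        b = modality_variance(trained_clf, clinical_cohort[0], T=5, seed=2)
        np.testing.assert_array_equal(a, b)

    def test_absent_modalities_get_infinite_variance(self, trained_clf,
                                                     clinical_cohort):
        s = clinical_cohort[0]
        from oncofuse import PatientSample
        masked = PatientSample(s.patient_id, np.zeros_like(s.image), s.genomic,
                               s.clinical, s.label, s.domain_id,
                               np.array([False, True, True]))
        sigma2 = modality_variance(trained_clf, masked, T=5, seed=0)
        assert sigma2[0] == np.inf
        assert np.isfinite(sigma2[1:]).all()

    def test_single_present_modality_weight_is_one(self, trained_clf,
                                                   clinical_cohort):
        s = clinical_cohort[0]
        from oncofuse import PatientSample
        masked = PatientSample(s.patient_id, np.zeros_like(s.image),
                               np.zeros_like(s.genomic), s.clinical, s.label,
                               s.domain_id, np.array([False, False, True]))
        sigma2 = modality_variance(trained_clf, masked, T=5, seed=0)
        np.testing.assert_allclose(inverse_variance_weights(sigma2), [0, 0, 1])


class TestInverseVarianceWeights:
    def test_equal_variances_give_equal_weights(self):
        np.testing.assert_allclose(inverse_variance_weights([2.0, 2.0, 2.0]),
                                   1 / 3, atol=1e-12)

    def test_hand_arithmetic_one_and_four(self):
        np.testing.assert_allclose(inverse_variance_weights([1.0, 4.0]),
                                   [0.8, 0.2], atol=1e-12)

    def test_infinite_variance_gets_zero_weight(self):
        np.testing.assert_allclose(
            inverse_variance_weights([1.0, np.inf, np.inf]), [1, 0, 0])

    def test_all_infinite_raises(self):
        with pytest.raises(ValueError, match="infinite"):
            inverse_variance_weights([np.inf, np.inf])

    def test_all_zero_falls_back_to_equal_weights(self):
        np.testing.assert_allclose(inverse_variance_weights([0.0, 0.0]), 0.5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_closed_form_on_random_positives(self, seed):
        rng = np.random.default_rng(seed)
        sigma2 = rng.uniform(0.01, 10.0, size=int(rng.integers(2, 6)))
        w = inverse_variance_weights(sigma2)
        expected = (1 / sigma2) / np.sum(1 / sigma2)
        np.testing.assert_allclose(w, expected, atol=1e-12)
        assert abs(w.sum() - 1.0) <= 1e-9 and (w >= 0).all()

    def test_monotone_decreasing_in_own_variance(self):
        base = np.array([1.0, 2.0, 3.0])
        w0 = inverse_variance_weights(base)[0]
        base_up = base.copy()
        base_up[0] *= 1.5
        assert inverse_variance_weights(base_up)[0] < w0


class TestUncertaintyWeightedFuse:
    def embeddings(self, vectors):
        mods = ["image", "genomic", "clinical"]
        return [ModalityEmbedding(np.asarray(v, float), mods[i])
                for i, v in enumerate(vectors)]

    def test_selection_and_fixed_point(self):
        embs = self.embeddings([[2, 0], [0, 2]])
        np.testing.assert_array_equal(uncertainty_weighted_fuse(embs, [1, 0]), [2, 0])
        same = self.embeddings([[3, 3]] * 2)
        np.testing.assert_allclose(uncertainty_weighted_fuse(same, [0.5, 0.5]), [3, 3])

    def test_hand_arithmetic(self):
        embs = self.embeddings([[2, 0], [0, 2]])
        np.testing.assert_allclose(uncertainty_weighted_fuse(embs, [0.8, 0.2]),
                                   [1.6, 0.4])


class TestEntropies:
    def test_one_hot_entropy_is_zero(self):
        assert prediction_entropy([0.0, 1.0, 0.0]) == 0.0
        assert attention_entropy([1.0, 0.0]) == 0.0

    def test_uniform_entropy_closed_form(self):
        assert prediction_entropy(np.full(4, 0.25)) == pytest.approx(np.log(4))
        assert prediction_entropy(np.full(4, 0.25), normalized=True) == \
            pytest.approx(1.0)

    def test_permutation_invariance(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        assert prediction_entropy(p) == pytest.approx(
            prediction_entropy(p[::-1]), abs=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            prediction_entropy([-0.1, 1.1])


class TestCalibrationLoss:
    @pytest.mark.parametrize("k,m", [(2, 3), (4, 2), (5, 3), (3, 3)])
    def test_uniform_uniform_is_zero_for_any_sizes(self, k, m):
        assert calibration_loss(np.full(k, 1 / k), np.full(m, 1 / m)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_one_hot_one_hot_is_zero(self):
        assert calibration_loss([1.0, 0.0], [0.0, 1.0, 0.0]) == 0.0

    def test_uniform_vs_one_hot_is_one(self):
        assert calibration_loss([0.5, 0.5], [1.0, 0.0, 0.0]) == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.dirichlet(np.ones(int(rng.integers(2, 6))))
        a = rng.dirichlet(np.ones(3))
        val = calibration_loss(y, a)
        assert 0.0 <= val <= 1.0

    def test_positive_on_mismatched_entropies(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            y = rng.dirichlet(np.ones(4))
            a = np.zeros(3)
            a[rng.integers(0, 3)] = 1.0  # sharp attention
            if prediction_entropy(y, normalized=True) > 1e-6:
                assert calibration_loss(y, a) > 0
                hits += 1
        assert hits > 0
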