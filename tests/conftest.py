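"""Shared fixtures: small seeded cohorts and a trained desk-scale classifier."""

import numpy as np
import pytest

from oncofuse import CohortConfig, MultimodalFusionClassifier, generate_cohort


@pytest.fixture(scope="session")
def clinical_cohort():
    """Cohort whose signal lives only in the clinical modality."""
    return generate_cohort(
        CohortConfig(n_patients=120, n_classes=2, informativeness=(0.0, 0.0, 1.0),
                     seed=11)
    )


@pytest.fixture(scope="session")
def trained_clf(clinical_cohort):
    """A quickly trained fusion classifier shared by read-only tests."""
    clf = MultimodalFusionClassifier(
        n_epochs=8, batch_size=32, learning_rate=2e-3, vocab_size=12,
        random_state=0,
    )
    clf.fit(clinical_cohort)
    return clf


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
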