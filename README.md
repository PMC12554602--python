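# oncofuse

Multimodal diagnostic modeling for oncology cohorts: attention-based fusion
of imaging, genomic and clinical data with adversarial domain adaptation,
Monte-Carlo-dropout uncertainty, an entropy-matching calibration loss, and a
Q-learning treatment-policy learner — all runnable offline at desk scale on
a bundled synthetic cohort generator.

## Who this is for

Researchers in computational oncology and clinical machine learning who want
a small, fully seeded, dependency-light reference implementation of a
multimodal fusion diagnostic stack: every component is exercised end-to-end
on synthetic cohorts, with closed-form and brute-force oracles standing
behind the numerics.

## The model

Each patient carries an image `X ∈ R^{H×W×C}`, a genomic token sequence
`g ∈ {0..V−1}^m` and a clinical vector `c ∈ R^p`. Modality-specific encoders
map each stream into a shared latent space `R^d`:

* image: strided CNN → global average pooling → linear head;
* genomic: token embedding + sinusoidal positional code → multi-head
  self-attention blocks (`softmax(QKᵀ/√d_k)V` per head) → mean pool → linear;
* clinical: MLP with dropout.

The embeddings `Z_i` are fused by learned attention,

    e_i = wᵀZ_i,   α_i = softmax over present modalities,
    Z_fused = Σ_i α_i Z_i,   ŷ = softmax(W_out Z_fused + b_out),

with absent modalities excluded from the softmax (weight exactly 0, no
imputation). Training minimizes cross-entropy plus the structured penalty
`λ‖w‖² + β‖W_out‖²_F` and optional weighted auxiliary terms: a triplet
contrastive loss aligning same-patient cross-modal embeddings, an
adversarial domain-adaptation objective
`E_s[log D(F(x_s))] + E_t[log(1−D(F(x_t)))]` (alternating updates or a
gradient-reversal layer), a cross-domain consistency penalty
`‖f(x_s)−f(x_t)‖²`, and a calibration loss `|H(ŷ) − A(α)|` matching
normalized prediction entropy to normalized attention entropy.

At inference, keeping dropout active over `T` stochastic passes yields a
posterior-predictive mean and per-class variance; probing one modality at a
time gives per-modality variances `σ_i²` and inverse-variance evidence
weights `w_i = (1/σ_i²)/Σ_j(1/σ_j²)`, an alternative fusion rule.

Treatment planning is modeled as a finite MDP `(S, A, P, r, γ)` over patient
health states; tabular Q-learning with experience replay, a target table and
ε-greedy exploration minimizes the entropy-regularized TD loss
`E[(Q(s,a) − (r + γ max_a' Q(s',a')))²] − λ_H H(π)`, and synchronous value
iteration provides the exact `Q*` oracle.

All differentiable components run on a small, self-contained reverse-mode
autodiff engine over numpy float64 arrays (`oncofuse._autodiff`), so
training is deterministic given a seed.

## Worked example

```python
import numpy as np
from oncofuse import (CohortConfig, MultimodalFusionClassifier,
                      generate_cohort, split_cohort, evaluate, attention_report)

cohort = generate_cohort(CohortConfig(n_patients=500, n_classes=2,
                                      informativeness=(0.0, 0.0, 1.0), seed=0))
train, _, test = split_cohort(cohort, seed=0, fractions=(0.7, 0.0, 0.3))
clf = MultimodalFusionClassifier(n_epochs=20, batch_size=32,
                                 learning_rate=2e-3, vocab_size=12,
                                 random_state=0).fit(train)
report = evaluate(clf, test)
print(report.accuracy, report.macro_f1, report.macro_auc)
print(clf.attention_weights(test).mean(axis=0))
```

prints

```
1.0 1.0 1.0
[0.275 0.274 0.451]
```

The cohort puts all class signal in the clinical stream
(`informativeness=(0, 0, 1)`), and the held-out metrics confirm the signal
is recovered perfectly; the mean attention weights show the model learned to
lean on the clinical modality (0.451) over the two pure-noise streams
(~0.27 each). A per-patient case report adds uncertainty and attribution:

```python
case = attention_report(clf, test[0], T=20, seed=0)
```

yields (abridged)

```json
{
  "attention_weights": [0.169, 0.159, 0.672],
  "inverse_variance_weights": [0.124, 0.311, 0.565],
  "probabilities": [0.915, 0.085],
  "predicted_class": 0,
  "normalized_entropy": 0.420
}
```

— for this patient both the attention map and the inverse-variance evidence
weights favor the clinical stream, and the prediction is made with moderate
normalized entropy. The same flows are available from the shell via the
`oncofuse` CLI (`generate`, `train`, `evaluate`, `predict`, `ablate`,
`policy train`, `diag mmd`).

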