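# Methods

This note records the modeling choices, parameter conventions and known
limitations of the package, in the spirit of a model-description appendix.

## Problem setting

The package targets multimodal diagnosis in oncology: each patient is
observed through up to three streams — a medical image, a genomic token
sequence, and a structured clinical vector — and the task is K-class
classification with (a) robustness to acquisition shift between a source and
a target site, (b) robustness to missing modalities, (c) calibrated
uncertainty, and (d) a downstream treatment-policy recommendation. Real
hospital datasets are out of scope; a seeded synthetic cohort generator
emulates the *structure* of such data so that every mechanism is testable
offline.

## Synthetic cohorts

Each class `k` owns a latent prototype `u_k ∈ R^16` drawn once per cohort.
Modalities render the same prototype through fixed, documented maps:

* **image** — `u_k` projected onto a low-spatial-frequency separable cosine
  basis (smooth intensity patterns, the kind a small CNN can read), plus
  i.i.d. Gaussian pixel noise with standard deviation `noise_sd`;
* **genomic** — tokens drawn i.i.d. from a class-conditional categorical
  whose logits are a fixed linear projection of `u_k`, plus logit noise;
  sequence order itself carries no class information;
* **clinical** — a fixed affine map of `u_k` plus Gaussian noise.

Per-modality informativeness weights in `[0, 1]` scale the prototype's
contribution; weight 0 makes the modality pure noise, giving an exact
chance-level control. Domain shift is an affine perturbation
(`scale_shift`, `mean_shift`) of image intensities and clinical features for
a `target_fraction` of patients — an acquisition effect, deliberately not a
change in biology, so token identities are untouched. Missingness drops each
modality flag independently at a given rate, restoring one uniformly chosen
modality when all three would vanish (the architecture needs one input
stream); absent content is zero-filled and the mask is authoritative.

Desk-scale defaults — 8×8×1 images, 16 tokens over a 12-symbol vocabulary,
8 clinical features, `noise_sd = 0.5`, informativeness 0.6 per modality —
were chosen once as the smallest sizes at which each encoder still has
non-trivial structure to learn (multiple conv strides, multiple attention
tokens) while a full training run takes seconds. Identical configurations
(including the seed) generate bit-identical cohorts.

What the generator does *not* emulate: real class imbalance, correlated
noise between modalities, informative missingness, label noise, survival
outcomes, or the visual statistics of histology. Passing tests therefore
demonstrate mechanism correctness and directional behavior (e.g. attention
concentrating on the informative stream), not clinical performance.

## Architecture and numerics

All trainable components run on a package-local reverse-mode autodiff engine
over float64 numpy arrays. The engine implements exactly the primitives the
architectures need (broadcast arithmetic, batched matmul, im2col
convolution, gather/scatter indexing, softmax/logsumexp with a detached
per-row max, an exact erf-based GELU, inverted dropout, and a
gradient-reversal op); gradients are verified against central finite
differences in the test suite. Float64 plus explicit `numpy.random.Generator`
seeding makes every training run bit-reproducible.

Encoders: image — two stride-2 valid convolutions (8 then 16 channels,
3×3 kernels), ReLU, global average pooling, linear head to `d = 32`;
genomic — 16-dimensional token embedding + fixed sinusoidal positional code,
two residual blocks of 2-head self-attention (head dimension 8) each
followed by a residual 2×-wide MLP, mean pooling, linear head; clinical —
one 32-unit hidden layer with ReLU and dropout 0.1, linear head. ReLU is the
default nonlinearity (GELU available). Mean pooling is the default token
pooling (first-token available); with positional encoding disabled and mean
pooling the genomic encoder is exactly permutation-invariant, which the
tests exploit.

Fusion masks absent modalities by adding −1e30 to their attention scores
before the softmax, which underflows to an exact zero weight — absent
streams contribute neither signal nor gradient, and no imputation occurs.

### Objective

Cross-entropy (ε-clipped at 1e-12 in the functional form) plus the
structured penalty `λ‖w‖² + β‖W_out‖²_F` on the attention vector and
classifier head (defaults `λ = β = 1e-3`); a global weight-decay option on
all parameters is available as the alternative convention. Auxiliary terms
each default to weight 0.1 when enabled:

* **contrastive** — per-anchor triplets: anchor and positive are two
  modality embeddings of the same patient, the negative the anchor's
  modality from a different-label patient; margin 1.0. The implemented
  ordering `max(0, τ + ‖a−pos‖² − ‖a−neg‖²)` pulls same-patient views
  together; the opposite sign convention is retained behind a `literal` flag
  for comparison but rewards anchor–positive separation and is not used.
* **calibration** — `|H_norm(ŷ) − A_norm(α)|` with each entropy normalized by
  the log of its own length, since K classes and M modalities otherwise put
  the two entropies on different scales; a raw-entropy mode exists. For a
  patient with a single present modality the attention entropy is defined
  as 0. The term is part of the training objective by default (weight 0.1).
* **adversarial domain adaptation** — a 2-layer, width-32 sigmoid
  discriminator on fused embeddings. Default is alternating updates
  (discriminator ascent on `L_DA`, then encoder descent on task + `L_DA`);
  a gradient-reversal mode folds both into one backward pass. Off by default
  (needs two domains).
* **consistency** — squared prediction distance on source/target pairs.
  Real cohorts provide no pairing, so pairs are class-matched at random;
  in synthetic data same-class patients share a latent prototype, making
  class-matching the natural analogue of prototype nearest-neighbor pairing.

Optimization: Adam (β₁ = 0.9, β₂ = 0.999), initial learning rate 2e-4 with
cosine annealing, batch 64 as the full-scale convention; the desk-scale
recipe used throughout the tests and the acceptance script is 20 epochs,
batch 32, learning rate 2e-3, which reaches ceiling accuracy on the
synthetic cohorts in a few seconds. Modality dropout (training-time masking
with at-least-one retention) is available as an augmentation; an optional
EMA of the weights (decay 0.99) can replace the final parameters.
Divergence (non-finite loss) aborts with a diagnostic.

## Uncertainty

MC-dropout keeps the dropout sites (clinical encoder, fused representation)
active for `T` seeded passes; the mean is the predictive distribution, the
per-class empirical variance the epistemic-uncertainty estimate. Per-modality
variance `σ_i²` is the class-averaged MC variance of the *unimodal*
prediction (other modalities masked), a deliberately local probe of each
stream's reliability; an ensembling alternative would average independently
seeded models and is not implemented. Inverse-variance weights follow
`w_i ∝ 1/σ_i²` with the conventions: infinite variance (absent modality) →
weight 0; all variances zero (a dropout-free model) → equal weights over the
zero entries, resolving the 0/0 limit. How attention weights and
inverse-variance weights should combine is genuinely open; the package
treats them as selectable fusion strategies (attention during training,
inverse-variance available at inference, and a renormalized product) rather
than committing to a composition.

## Treatment policy

The policy learner is tabular: states and actions are small finite sets, the
Q-table is the parameter, and the entropy-regularized TD loss is descended
with SGD on uniformly-without-replacement replay batches (capacity 4000,
batch 32), a hard-copied target table every 100 steps, and ε decaying
linearly 1.0 → 0.05 over 5000 steps. Q-learning defines no explicit policy,
so the entropy term reads the policy as `softmax(Q(s,·)/temperature)`
(temperature 1). Greedy ties break to the lowest action index. Two fixture
MDPs ship with the package: a deterministic 4-state chain used to verify
convergence to the value-iteration `Q*` (sup-norm < 0.05 after 2000
episodes; in practice the gap is at machine precision), and a 6-state
toy disease-course MDP (remission / stable / two progression stages /
toxicity / terminal; standard, intensified, supportive actions) whose
rewards are positive for response and negative for toxicity-driven
hospitalization. A distributional-RL reading of the return is mentioned in
the surrounding literature without an algorithmic specification and is not
implemented. A small-network Q-function over fused patient embeddings is a
natural extension of the tabular learner; the tabular form is the supported
and tested path.

## Evaluation conventions

Accuracy, macro (unweighted) recall, macro F1, and macro one-vs-rest AUC,
computed through scikit-learn; a class absent from an evaluation cohort is
excluded from the macro averages with a logged warning. Splits are seeded
patient-level shuffles, 70/15/15 by default. Replication uses 3 seeds.
Ablation variants toggle exactly one mechanism each: uniform-mean fusion in
place of attention; a single shared MLP on flattened inputs in place of the
three tailored encoders; adaptation terms off; the policy stage skipped; and
a combined CNN+MLP-style baseline.

## Known limitations

* The autodiff engine is dense-float64 and single-threaded by design; it is
  sized for desk-scale experiments, not GPU-scale training.
* Unimodal variance probing conflates a modality's informativeness with its
  sensitivity to dropout noise; ensembling would disentangle these.
* The synthetic generator's independence assumptions (noise independent
  across modalities, missingness independent of label) are favorable; the
  directional results proven here may shrink under correlated real-world
  corruption.
* The consistency term's class-matched pairing requires labels on the target
  domain and is therefore only meaningful in the synthetic setting.
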