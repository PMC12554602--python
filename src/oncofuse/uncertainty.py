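"""MC-dropout predictive distributions and uncertainty-weighted fusion.

Keeping dropout active at inference and averaging ``T`` stochastic forward
passes approximates the posterior predictive distribution; the across-pass
variance estimates epistemic uncertainty.  Per-modality reliability is probed
by predicting from one modality at a time (the others masked absent) and
summarizing the MC variance; the resulting variances feed inverse-variance
convex weights, an evidence-combination rule that lets the most reliable
modality dominate the fused representation.

The entropy-matching calibration loss compares the (normalized) entropy of
the predicted class distribution with the (normalized) entropy of the
attention map: a model should be uncertain when its attention is diffuse and
confident only when it is sharply focused.  Natural logarithms throughout;
normalization divides each entropy by the log of its own length so
distributions of different sizes are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


__all__ = [
    "PredictiveEstimate",
    "mc_dropout_predict",
    "modality_variance",
    "inverse_variance_weights",
    "uncertainty_weighted_fuse",
    "attention_entropy",
    "prediction_entropy",
    "calibration_loss",
]


@dataclass
class PredictiveEstimate:
    """MC-dropout summary for one sample (or a stack of samples)."""

    mean: np.ndarray            # (K,) mean predicted probabilities
    per_class_variance: np.ndarray
    entropy: float              # Shannon entropy of the mean, in nats
    n_passes: int
    seed: int


def _entropy(p: np.ndarray, normalized: bool = False) -> float:
    """Shannon entropy with the 0 log 0 = 0 convention (natural log)."""
    p = np.asarray(p, dtype=np.float64)
    if (p < 0).any():
        raise ValueError("entropy requires nonnegative entries")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if normalized:
        h = h / np.log(len(p)) if len(p) > 1 else 0.0
    return h


def prediction_entropy(y_hat: np.ndarray, normalized: bool = False) -> float:
    """Entropy of a predicted class distribution."""
    return _entropy(y_hat, normalized=normalized)


def attention_entropy(alpha: np.ndarray, normalized: bool = False) -> float:
    """Entropy of an attention map (absent-modality zeros contribute 0)."""
    return _entropy(alpha, normalized=normalized)


def calibration_loss(y_hat: np.ndarray, alpha: np.ndarray,
                     normalized: bool = True) -> float:
    """|H(y_hat) - A(alpha)|, by default on length-normalized entropies.

    With normalization both entropies live in [0, 1], so the loss is
    well-scaled even when the number of classes differs from the number of
    modalities; ``normalized=False`` gives the raw-entropy comparison.
    """
    return abs(prediction_entropy(y_hat, normalized)
               - attention_entropy(alpha, normalized))


def mc_dropout_predict(model, X, T: int, seed: int = 0,
                       mask: np.ndarray | None = None) -> PredictiveEstimate:
    """Average ``T`` stochastic forward passes with dropout kept active.

    ``model`` is a fitted :class:`~oncofuse.fusion.MultimodalFusionClassifier`;
    ``X`` one sample or a list (a single-sample list returns that sample's
    estimate; larger lists return stacked arrays).
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    arrays = model._as_arrays(_listify(X))
    rng = np.random.default_rng(seed)
    passes = np.stack([
        model.net_.forward(arrays, rng=rng, dropout_active=True,
                           mask=mask)["probs"].data
        for _ in range(T)
    ])  # (T, N, K)
    mean = passes.mean(axis=0)
    variance = passes.var(axis=0)
    if mean.shape[0] == 1:
        mean, variance = mean[0], variance[0]
        entropy = _entropy(mean)
    else:
        entropy = float(np.mean([_entropy(row) for row in mean]))
    return PredictiveEstimate(mean=mean, per_class_variance=variance,
                              entropy=entropy, n_passes=T, seed=seed)


def modality_variance(model, X, T: int, seed: int = 0) -> np.ndarray:
    """Per-modality predictive variance via unimodal MC-dropout probes.

    For each *present* modality the sample is re-predicted using only that
    modality; sigma_i^2 is the class-averaged MC variance of that unimodal
    prediction.  Absent modalities get ``+inf`` (weight 0 downstream).
    """
    if T < 2:
        raise ValueError(f"modality variance needs T >= 2, got {T}")
    samples = _listify(X)
    arrays = model._as_arrays(samples)
    base_mask = arrays["mask"]
    n = base_mask.shape[0]
    if not base_mask.any(axis=1).all():
        raise ValueError("every sample needs at least one present modality")
    sigma2 = np.full((n, 3), np.inf)
    for m in range(3):
        rows = np.flatnonzero(base_mask[:, m])
        if len(rows) == 0:
            continue
        probe = np.zeros_like(base_mask)
        probe[:, m] = base_mask[:, m]
        probe[~probe.any(axis=1), m] = True  # rows skipped below anyway
        est = mc_dropout_predict(model, arrays, T=T, seed=seed + m, mask=probe)
        var = np.atleast_2d(est.per_class_variance)
        sigma2[rows, m] = var[rows].mean(axis=1)
    single = not isinstance(X, (list, tuple, dict)) and n == 1
    return sigma2[0] if single else sigma2


def inverse_variance_weights(sigma2) -> np.ndarray:
    """Convex weights ``w_i = (1/sigma_i^2) / sum_j (1/sigma_j^2)``.

    ``+inf`` variance gives weight 0; all-``inf`` is an error.  If every
    finite variance is 0 (a dropout-free model), the degenerate 0/0 is
    resolved by equal weights over the zero-variance entries.
    """
    sigma2 = np.asarray(sigma2, dtype=np.float64)
    if (sigma2 < 0).any():
        raise ValueError("variances must be nonnegative")
    finite = np.isfinite(sigma2)
    if not finite.any():
        raise ValueError("all modality variances are infinite; no evidence to weight")
    zeros = finite & (sigma2 == 0.0)
    if zeros.any():
        weights = np.zeros_like(sigma2)
        weights[zeros] = 1.0 / zeros.sum()
        return weights
    inv = np.where(finite, 1.0 / np.where(finite, sigma2, 1.0), 0.0)
    return inv / inv.sum()


def uncertainty_weighted_fuse(embeddings, weights) -> np.ndarray:
    """``sum_i w_i Z_i`` — same contract as attention fusion with w_i for alpha_i."""
    from .fusion import fuse  # same convex-combination implementation

    return fuse(embeddings, weights)


def _listify(X):
    if isinstance(X, dict):
        return X
    if isinstance(X, (list, tuple)):
        return list(X)
    return [X]
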