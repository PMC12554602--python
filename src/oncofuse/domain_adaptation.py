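"""Adversarial domain alignment, kernel MMD and cross-domain consistency.

A domain discriminator ``D`` tries to tell source-domain fused embeddings
from target-domain ones; the encoder is trained to confuse it, which aligns
the latent feature distributions of the two acquisition domains.  The
adversarial objective is

    L_DA = E_s[log D(F(x_s))] + E_t[log(1 - D(F(x_t)))],

maximized over ``D`` and minimized over the encoder in alternating updates.
Maximum mean discrepancy (Gaussian kernel, biased estimator) serves both as
an alternative divergence and as the diagnostic used to verify the effect of
adaptation.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist

from . import _autodiff as ad
from . import nn
from ._autodiff import Tensor

_EPS = 1e-12

__all__ = [
    "DomainDiscriminator",
    "adversarial_da_loss",
    "mmd",
    "median_heuristic_bandwidth",
    "consistency_loss",
    "adversarial_training_step",
]


class DomainDiscriminator(nn.Module):
    """2-layer MLP scoring the probability a fused embedding is source-domain."""

    def __init__(self, input_dim: int, hidden: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.fc1 = nn.Linear(input_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, 1, rng)

    def forward_tensor(self, z: Tensor) -> Tensor:
        """Differentiable path: (N, d) -> (N,) probabilities in (0, 1)."""
        h = ad.relu(self.fc1(z))
        out = ad.sigmoid(self.fc2(h))
        return ad.reshape(out, (z.shape[0],))

    def __call__(self, z: np.ndarray) -> np.ndarray:
        probs = self.forward_tensor(Tensor(np.atleast_2d(z))).data
        return np.clip(probs, _EPS, 1.0 - _EPS)


def adversarial_da_loss(d_source, d_target) -> float:
    """``mean log D(source) + mean log(1 - D(target))``.

    The discriminator maximizes this; the encoder minimizes it.  Probabilities
    at exactly 0 or 1 are clipped to keep the logs finite (with a warning).
    """
    d_source = np.atleast_1d(np.asarray(d_source, dtype=np.float64))
    d_target = np.atleast_1d(np.asarray(d_target, dtype=np.float64))
    if ((d_source <= 0) | (d_source >= 1)).any() or \
       ((d_target <= 0) | (d_target >= 1)).any():
        warnings.warn("discriminator probabilities at {0,1} clipped to (eps, 1-eps)",
                      RuntimeWarning, stacklevel=2)
    d_source = np.clip(d_source, _EPS, 1.0 - _EPS)
    d_target = np.clip(d_target, _EPS, 1.0 - _EPS)
    return float(np.mean(np.log(d_source)) + np.mean(np.log(1.0 - d_target)))


def median_heuristic_bandwidth(z_source, z_target) -> float:
    """Median pairwise distance over the pooled sample (a standard default)."""
    pooled = np.vstack([np.atleast_2d(z_source), np.atleast_2d(z_target)])
    if len(pooled) < 2:
        return 1.0
    dists = cdist(pooled, pooled)
    upper = dists[np.triu_indices(len(pooled), k=1)]
    med = float(np.median(upper))
    return med if med > 0 else 1.0


def mmd(z_source, z_target, bandwidth: float | None = None) -> float:
    """Biased squared maximum mean discrepancy with a Gaussian kernel.

    ``MMD^2 = mean k(s, s') + mean k(t, t') - 2 mean k(s, t)`` with
    ``k(a, b) = exp(-||a - b||^2 / (2 sigma^2))``.  ``bandwidth=None`` uses
    the median heuristic over the pooled samples.
    """
    zs = np.atleast_2d(np.asarray(z_source, dtype=np.float64))
    zt = np.atleast_2d(np.asarray(z_target, dtype=np.float64))
    if zs.shape[0] == 0 or zt.shape[0] == 0:
        raise ValueError("mmd requires nonempty sample sets on both sides")
    sigma = median_heuristic_bandwidth(zs, zt) if bandwidth is None else float(bandwidth)
    if sigma <= 0:
        raise ValueError(f"bandwidth must be > 0, got {sigma}")

    def kernel_mean(a, b):
        return float(np.mean(np.exp(-cdist(a, b, "sqeuclidean") / (2.0 * sigma ** 2))))

    return kernel_mean(zs, zs) + kernel_mean(zt, zt) - 2.0 * kernel_mean(zs, zt)


def consistency_loss(pred_source, pred_target) -> float:
    """Mean squared Euclidean distance between paired prediction vectors."""
    ps = np.atleast_2d(np.asarray(pred_source, dtype=np.float64))
    pt = np.atleast_2d(np.asarray(pred_target, dtype=np.float64))
    if ps.shape != pt.shape:
        raise ValueError(
            f"consistency loss needs paired predictions, got {ps.shape} vs {pt.shape}"
        )
    return float(np.mean(np.sum((ps - pt) ** 2, axis=1)))


def adversarial_training_step(net, discriminator, batch, domains, mode: str,
                              labels=None, encoder_lr: float = 1e-3,
                              discriminator_lr: float = 1e-3,
                              rng: np.random.Generator | None = None) -> None:
    """One alternating update on ``net`` (encoder side) or ``discriminator``.

    ``mode='discriminator_step'`` ascends the adversarial objective with
    respect to the discriminator only; ``mode='encoder_step'`` descends the
    task loss plus the adversarial term with respect to the encoder only.
    The non-updated component is left bit-for-bit unchanged.
    """
    if mode not in ("discriminator_step", "encoder_step"):
        raise ValueError(f"mode must be 'discriminator_step' or 'encoder_step', got {mode!r}")
    rng = rng or np.random.default_rng(0)
    domains = np.asarray(domains)
    src = np.flatnonzero(domains == "source")
    tgt = np.flatnonzero(domains == "target")
    if len(src) == 0 or len(tgt) == 0:
        raise ValueError("batch must contain both source and target samples")

    out = net.forward(batch, rng=rng, dropout_active=False)
    fused = Tensor(out["z_fused"].data) if mode == "discriminator_step" else out["z_fused"]
    d_all = discriminator.forward_tensor(fused)
    d_src = ad.getitem(d_all, (src,))
    d_tgt = ad.getitem(d_all, (tgt,))
    adv = ad.add(
        ad.tensor_mean(ad.log(ad.add(d_src, _EPS))),
        ad.tensor_mean(ad.log(ad.add(ad.mul(d_tgt, -1.0), 1.0 + _EPS))),
    )

    if mode == "discriminator_step":
        loss = ad.mul(adv, -1.0)  # ascend L_DA
        params = discriminator.parameters()
        lr = discriminator_lr
    else:
        loss = adv
        if labels is not None:
            loss = ad.add(ad.cross_entropy(out["logits"], np.asarray(labels)), loss)
        params = net.parameters()
        lr = encoder_lr

    net.zero_grad()
    discriminator.zero_grad()
    loss.backward()
    if not all(np.isfinite(p.grad).all() for p in params if p.grad is not None):
        raise RuntimeError("non-finite gradients in adversarial step")
    for p in params:
        if p.grad is not None:
            p.data = p.data - lr * p.grad
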