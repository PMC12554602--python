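"""Modality-specific encoders into a shared latent space.

Three encoders map the raw streams to length-``d`` embeddings:

* :class:`ImageEncoder` — strided CNN, global average pooling, linear head;
* :class:`GenomicEncoder` — token embedding + fixed sinusoidal positional
  code, a stack of residual multi-head self-attention blocks, mean pooling
  over tokens, linear head;
* :class:`ClinicalEncoder` — MLP with nonlinearity and dropout.

The module also exposes :func:`scaled_dot_attention` (the primitive each
attention head applies) and :func:`contrastive_alignment_loss`, a triplet
margin loss that pulls same-patient cross-modal embeddings together and
pushes mismatched patients apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from . import nn
from ._autodiff import Tensor

__all__ = [
    "EncoderConfig",
    "ModalityEmbedding",
    "ImageEncoder",
    "GenomicEncoder",
    "ClinicalEncoder",
    "scaled_dot_attention",
    "contrastive_alignment_loss",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters shared by the three encoders (desk-scale defaults)."""

    shared_dim: int = 32
    # image CNN
    conv_channels: tuple = (8, 16)
    kernel_size: int = 3
    stride: int = 2
    # genomic transformer
    embed_dim: int = 16
    n_heads: int = 2
    n_layers: int = 2
    positional_encoding: bool = True
    pooling: str = "mean"  # or "first"
    # clinical MLP
    hidden_widths: tuple = (32,)
    activation: str = "relu"  # or "gelu"
    dropout_rate: float = 0.1

    def validate(self) -> None:
        if self.shared_dim < 1:
            raise ValueError(f"shared_dim must be >= 1, got {self.shared_dim}")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} must divide into {self.n_heads} heads"
            )
        if self.embed_dim // self.n_heads < 1:
            raise ValueError("head dimension must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.pooling not in ("mean", "first"):
            raise ValueError(f"pooling must be 'mean' or 'first', got {self.pooling!r}")
        if self.activation not in ("relu", "gelu"):
            raise ValueError(f"activation must be 'relu' or 'gelu', got {self.activation!r}")


@dataclass
class ModalityEmbedding:
    """A point in the shared latent space, tagged with provenance."""

    vector: np.ndarray
    modality: str
    patient_id: str = ""
    present: bool = True

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.isfinite(self.vector).all():
            raise ValueError(f"non-finite embedding for modality {self.modality!r}")


def _activation(name: str):
    return ad.relu if name == "relu" else ad.gelu


def scaled_dot_attention(Q, K, V, d_k: float | None = None):
    """Row-wise ``softmax(Q K^T / sqrt(d_k)) V``.

    Accepts plain arrays (returns an array) or autodiff tensors (returns a
    tensor, differentiable).  ``Q``/``K``: (..., T, d_k); ``V``: (..., T, d_v).
    Each attention row is a convex combination of the rows of ``V``.
    """
    tensor_in = isinstance(Q, Tensor) or isinstance(K, Tensor) or isinstance(V, Tensor)
    Qt, Kt, Vt = ad.as_tensor(Q), ad.as_tensor(K), ad.as_tensor(V)
    for name, t in (("Q", Qt), ("K", Kt), ("V", Vt)):
        if not np.isfinite(t.data).all():
            raise ValueError(f"non-finite entries in {name}")
    if d_k is None:
        d_k = Qt.shape[-1]
    if d_k <= 0:
        raise ValueError(f"d_k must be positive, got {d_k}")
    scores = ad.mul(ad.matmul(Qt, ad.transpose(Kt, tuple(range(Kt.ndim - 2)) + (Kt.ndim - 1, Kt.ndim - 2))),
                    1.0 / np.sqrt(float(d_k)))
    out = ad.matmul(ad.softmax(scores, axis=-1), Vt)
    return out if tensor_in else out.data


def contrastive_alignment_loss(anchor, positive, negative, margin: float,
                               literal: bool = False):
    """Triplet margin loss aligning cross-modal views of the same patient.

    Default semantics: ``max(0, margin + ||a - pos||^2 - ||a - neg||^2)`` —
    same-patient views are pulled within ``margin`` of each other relative to
    mismatched views.  ``literal=True`` swaps the two distance terms
    (an alternative sign convention kept for comparison; it *rewards*
    anchor-positive separation and is not recommended).

    Accepts 1-D vectors or (N, d) batches; batched input returns the mean
    over rows.  Differentiable when given tensors.
    """
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    tensor_in = any(isinstance(x, Tensor) for x in (anchor, positive, negative))
    a, p, n = (ad.as_tensor(x) for x in (anchor, positive, negative))
    if not (a.shape == p.shape == n.shape):
        raise ValueError(
            f"shape mismatch: anchor {a.shape}, positive {p.shape}, negative {n.shape}"
        )
    d_pos = ad.tensor_sum(ad.power(ad.add(a, ad.mul(p, -1.0)), 2.0), axis=-1)
    d_neg = ad.tensor_sum(ad.power(ad.add(a, ad.mul(n, -1.0)), 2.0), axis=-1)
    gap = ad.add(d_neg, ad.mul(d_pos, -1.0)) if literal else ad.add(d_pos, ad.mul(d_neg, -1.0))
    loss = ad.tensor_mean(ad.relu(ad.add(gap, float(margin))))
    return loss if tensor_in else loss.item()


class ImageEncoder(nn.Module):
    """Strided CNN -> global average pooling -> linear map to the shared space."""

    def __init__(self, image_shape: tuple, config: EncoderConfig,
                 rng: np.random.Generator):
        h, w, c = image_shape
        self.image_shape = tuple(image_shape)
        self.convs = []
        c_in = c
        for c_out in config.conv_channels:
            self.convs.append(nn.Conv2d(c_in, c_out, config.kernel_size,
                                        config.stride, rng))
            c_in = c_out
        self.head = nn.Linear(c_in, config.shared_dim, rng)
        self._act = _activation(config.activation)

    def __call__(self, x: Tensor) -> Tensor:
        """``x``: (N, H, W, C) -> (N, d)."""
        if x.shape[1:] != self.image_shape:
            raise ValueError(
                f"image shape mismatch: expected {self.image_shape}, got {tuple(x.shape[1:])}"
            )
        for conv in self.convs:
            x = self._act(conv(x))
        pooled = ad.tensor_mean(x, axis=(1, 2))  # global average pooling
        return self.head(pooled)


class _SelfAttentionBlock(nn.Module):
    """Residual multi-head self-attention followed by a residual MLP."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        self.n_heads = int(n_heads)
        self.head_dim = dim // n_heads
        self.wq = nn.Linear(dim, dim, rng)
        self.wk = nn.Linear(dim, dim, rng)
        self.wv = nn.Linear(dim, dim, rng)
        self.wo = nn.Linear(dim, dim, rng)
        self.ff1 = nn.Linear(dim, 2 * dim, rng)
        self.ff2 = nn.Linear(2 * dim, dim, rng)

    def _split_heads(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        x = ad.reshape(x, (n, t, self.n_heads, self.head_dim))
        return ad.transpose(x, (0, 2, 1, 3))  # (N, h, T, d_k)

    def __call__(self, x: Tensor) -> Tensor:
        q = self._split_heads(self.wq(x))
        k = self._split_heads(self.wk(x))
        v = self._split_heads(self.wv(x))
        attended = scaled_dot_attention(q, k, v, d_k=self.head_dim)
        n, h, t, dk = attended.shape
        merged = ad.reshape(ad.transpose(attended, (0, 2, 1, 3)), (n, t, h * dk))
        x = ad.add(x, self.wo(merged))
        return ad.add(x, self.ff2(ad.relu(self.ff1(x))))


class GenomicEncoder(nn.Module):
    """Transformer over genomic tokens, pooled to a single embedding."""

    def __init__(self, vocab_size: int, config: EncoderConfig,
                 rng: np.random.Generator):
        self.embedding = nn.Embedding(vocab_size, config.embed_dim, rng)
        self.blocks = [
            _SelfAttentionBlock(config.embed_dim, config.n_heads, rng)
            for _ in range(config.n_layers)
        ]
        self.head = nn.Linear(config.embed_dim, config.shared_dim, rng)
        self.positional_encoding = bool(config.positional_encoding)
        self.pooling = config.pooling
        self.embed_dim = config.embed_dim

    def __call__(self, tokens: np.ndarray) -> Tensor:
        """``tokens``: (N, m) integer array -> (N, d)."""
        x = self.embedding(tokens)
        if self.positional_encoding:
            x = ad.add(x, Tensor(nn.sinusoidal_positions(x.shape[1], self.embed_dim)))
        for block in self.blocks:
            x = block(x)
        if self.pooling == "mean":
            pooled = ad.tensor_mean(x, axis=1)
        else:
            pooled = ad.getitem(x, (slice(None), 0))
        return self.head(pooled)


class ClinicalEncoder(nn.Module):
    """MLP over the structured clinical vector, with dropout regularization."""

    def __init__(self, clinical_dim: int, config: EncoderConfig,
                 rng: np.random.Generator):
        self.clinical_dim = int(clinical_dim)
        widths = [clinical_dim, *config.hidden_widths]
        self.layers = [nn.Linear(widths[i], widths[i + 1], rng)
                       for i in range(len(widths) - 1)]
        self.head = nn.Linear(widths[-1], config.shared_dim, rng)
        self.dropout = nn.Dropout(config.dropout_rate)
        self._act = _activation(config.activation)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None,
                 train: bool = False) -> Tensor:
        """``x``: (N, p) -> (N, d); dropout active only when ``train``."""
        if x.shape[-1] != self.clinical_dim:
            raise ValueError(
                f"clinical vector length mismatch: expected {self.clinical_dim}, "
                f"got {x.shape[-1]}"
            )
        for layer in self.layers:
            x = self.dropout(self._act(layer(x)), rng, train)
        return self.head(x)
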