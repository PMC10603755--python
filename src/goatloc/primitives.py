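"""Channel-attention and normalization primitives.

Functional reference implementations of the squeeze-and-excitation (SE)
block, the exact-Gaussian GeLU activation and the per-pixel variant of
layer normalization, operating on ``(H, W, C)`` feature maps.  These are
the mathematical definitions; the trainable counterparts with backward
passes live in :mod:`goatloc.layers` and are tested against these.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, ndtr

__all__ = [
    "SEConfig",
    "LayerNormParams",
    "squeeze",
    "excite",
    "reweight",
    "se_block",
    "gelu",
    "layer_norm_pixelwise",
]


@dataclass
class SEConfig:
    """Weights of the excitation bottleneck.

    The squeeze vector ``z`` (length ``C``) is reduced to ``C // reduction``
    units by ``w1``, passed through ReLU, restored to ``C`` units by ``w2``
    and gated with a sigmoid.  Both layers are bias-free by default; set
    ``bias1``/``bias2`` to enable biases.
    """

    channels: int
    reduction: int = 4
    w1: np.ndarray = None  # (C//r, C)
    w2: np.ndarray = None  # (C, C//r)
    bias1: np.ndarray | None = None
    bias2: np.ndarray | None = None

    def __post_init__(self):
        if self.channels <= 0 or self.reduction <= 0:
            raise ValueError("channels and reduction must be positive")
        if self.channels % self.reduction != 0:
            raise ValueError(
                f"channels ({self.channels}) must be divisible by "
                f"reduction ({self.reduction})"
            )
        hidden = self.channels // self.reduction
        if self.w1 is None:
            self.w1 = np.zeros((hidden, self.channels))
        if self.w2 is None:
            self.w2 = np.zeros((self.channels, hidden))
        self.w1 = np.asarray(self.w1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        if self.w1.shape != (hidden, self.channels):
            raise ValueError(f"w1 must have shape {(hidden, self.channels)}")
        if self.w2.shape != (self.channels, hidden):
            raise ValueError(f"w2 must have shape {(self.channels, hidden)}")

    @classmethod
    def random(cls, channels: int, reduction: int = 4, rng=None, scale: float | None = None):
        """Kaiming-style random excitation weights."""
        rng = np.random.default_rng(rng)
        hidden = channels // reduction
        s1 = scale if scale is not None else np.sqrt(2.0 / channels)
        s2 = scale if scale is not None else np.sqrt(2.0 / max(hidden, 1))
        return cls(
            channels=channels,
            reduction=reduction,
            w1=rng.normal(0.0, s1, size=(hidden, channels)),
            w2=rng.normal(0.0, s2, size=(channels, hidden)),
        )


@dataclass
class LayerNormParams:
    """Per-channel affine parameters for pixelwise layer normalization."""

    gamma: np.ndarray
    beta: np.ndarray
    eps: float = 1e-6

    def __post_init__(self):
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.gamma.shape != self.beta.shape or self.gamma.ndim != 1:
            raise ValueError("gamma and beta must be 1-D vectors of equal length")
        if not self.eps > 0:
            raise ValueError("eps must be positive")

    @classmethod
    def identity(cls, channels: int, eps: float = 1e-6):
        return cls(np.ones(channels), np.zeros(channels), eps)


def _check_fm(fm: np.ndarray) -> np.ndarray:
    fm = np.asarray(fm, dtype=float)
    if fm.ndim != 3 or fm.size == 0:
        raise ValueError("feature map must be a non-empty (H, W, C) array")
    if not np.all(np.isfinite(fm)):
        raise ValueError("feature map contains non-finite values")
    return fm


def squeeze(fm: np.ndarray) -> np.ndarray:
    """Global average pool: z_c = mean over the H x W grid of channel c."""
    fm = _check_fm(fm)
    return fm.mean(axis=(0, 1))


def excite(z: np.ndarray, cfg: SEConfig) -> np.ndarray:
    """Bottleneck gating: s = sigmoid(W2 @ relu(W1 @ z)), entries in (0, 1)."""
    z = np.asarray(z, dtype=float)
    if z.shape != (cfg.channels,):
        raise ValueError(f"z has length {z.shape}, expected ({cfg.channels},)")
    h = cfg.w1 @ z
    if cfg.bias1 is not None:
        h = h + cfg.bias1
    h = np.maximum(h, 0.0)
    o = cfg.w2 @ h
    if cfg.bias2 is not None:
        o = o + cfg.bias2
    return expit(o)


def reweight(fm: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Scale each channel of the feature map by its excitation weight."""
    fm = _check_fm(fm)
    s = np.asarray(s, dtype=float)
    if s.shape != (fm.shape[2],):
        raise ValueError(
            f"weight vector length {s.shape} does not match {fm.shape[2]} channels"
        )
    return fm * s[None, None, :]


def se_block(fm: np.ndarray, cfg: SEConfig) -> np.ndarray:
    """Full squeeze -> excite -> reweight attention pass; shape preserved."""
    return reweight(fm, excite(squeeze(fm), cfg))


def gelu(x):
    """Gaussian Error Linear Unit, x * Phi(x).

    Uses the exact standard-normal CDF (erf form), not the tanh
    approximation.  Accepts scalars or arrays of any shape.
    """
    x = np.asarray(x, dtype=float)
    out = x * ndtr(x)
    return out if out.ndim else float(out)


def layer_norm_pixelwise(fm: np.ndarray, p: LayerNormParams) -> np.ndarray:
    """Normalize each pixel's channel vector to zero mean / unit variance.

    At every spatial position the statistics are computed over the C
    channels alone, so the result is independent of batch composition and
    of the other pixels.  A per-channel affine (gamma, beta) follows.
    """
    fm = _check_fm(fm)
    if p.gamma.shape[0] != fm.shape[2]:
        raise ValueError("affine parameter length must equal channel count")
    mu = fm.mean(axis=2, keepdims=True)
    var = fm.var(axis=2, keepdims=True)
    normed = (fm - mu) / np.sqrt(var + p.eps)
    return normed * p.gamma[None, None, :] + p.beta[None, None, :]
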