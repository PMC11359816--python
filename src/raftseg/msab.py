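"""Multiscale spatial attention block (MSAB).

A 1x1 projection produces stacked query/key/value maps (3C channels).
Each attention scale applies its own depthwise convolution to the stack,
flattens the map to tokens, splits Q/K/V along channels, rectifies Q and
K and computes softmax-free linear attention in the O(N d^2) association
order (K'^T V first).  The per-scale outputs are concatenated, projected
back to C channels by a 1x1 convolution, and summed with the input; a
BatchNorm + GeLU MLP with a second residual completes the block.

The printed attention product has no normalizer; the rectified-attention
mechanism it builds on is row-normalized, and the unnormalized form is
scale-divergent in practice, so the denominator ``q'(K'^T 1) + eps`` is
applied by default with ``unnormalized_attention=True`` available to
reproduce the bare product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, Module, Conv2d, BatchNorm2d, GELU, Sequential, concatenate

__all__ = ["AttentionConfig", "MSAB", "relu_linear_attention"]


@dataclass
class AttentionConfig:
    channels: int
    scales: tuple = (3, 5)
    epsilon: float = 1e-6
    mlp_expansion: int = 4
    unnormalized_attention: bool = False

    def validate(self) -> None:
        if self.channels < 1:
            raise ValueError(f"channels must be positive, got {self.channels}")
        if not self.scales:
            raise ValueError("scales must be non-empty")
        for s in self.scales:
            if s % 2 == 0 or s < 1:
                raise ValueError(f"attention scales must be odd and positive, got {s}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")


def relu_linear_attention(q, k, v, epsilon: float = 1e-6, normalized: bool = True):
    """Row-normalized ReLU linear attention on token matrices.

    ``q``, ``k``, ``v``: (..., N, d) arrays or Tensors.  Computes

        A_i = q'_i (K'^T V) / (q'_i (K'^T 1) + epsilon),   q' = relu(q), k' = relu(k)

    in the linear-cost association order (the d x d matrix K'^T V is
    formed first), which by associativity equals the quadratic form
    row_normalize(q' k'^T) v.  A single token attends only to itself, so
    N=1 with positive q, k returns v exactly; an all-non-positive query
    row yields zeros (the epsilon guards the denominator).
    """
    q = q if isinstance(q, Tensor) else Tensor(np.asarray(q))
    k = k if isinstance(k, Tensor) else Tensor(np.asarray(k))
    v = v if isinstance(v, Tensor) else Tensor(np.asarray(v))
    qp = q.relu()
    kp = k.relu()
    kt = kp.transpose(tuple(range(kp.ndim - 2)) + (kp.ndim - 1, kp.ndim - 2))
    kv = kt @ v                                   # (..., d, d)
    num = qp @ kv                                 # (..., N, d)
    if not normalized:
        return num
    ksum = kp.sum(axis=-2, keepdims=True)         # (..., 1, d)
    den = (qp * ksum).sum(axis=-1, keepdims=True) + epsilon
    return num / den


class MSAB(Module):
    """QKV projection, per-scale depthwise aggregation, linear attention,
    output projection + residual, BatchNorm + GeLU MLP + residual."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator | None = None):
        super().__init__()
        cfg.validate()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        c = cfg.channels
        self.qkv = Conv2d(c, 3 * c, 1, rng=rng)
        self.aggregators = Sequential(*[
            Conv2d(3 * c, 3 * c, s, padding=s // 2, groups=3 * c, rng=rng)
            for s in cfg.scales
        ])
        self.out_proj = Conv2d(len(cfg.scales) * c, c, 1, rng=rng)
        self.norm = BatchNorm2d(c)
        e = cfg.mlp_expansion
        self.mlp = Sequential(
            Conv2d(c, e * c, 1, rng=rng),
            GELU(),
            Conv2d(e * c, c, 1, rng=rng),
        )

    def project_qkv(self, x: Tensor) -> Tensor:
        """1x1 projection producing the stacked (Q, K, V) map with 3C channels."""
        return self.qkv(x)

    def multiscale_aggregate(self, qkv: Tensor) -> list:
        """One same-padded depthwise convolution of the QKV stack per scale."""
        return [agg(qkv) for agg in self.aggregators]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"MSAB built for {self.cfg.channels} channels, got {x.shape[1]}")
        b, c, h, w = x.shape
        qkv = self.project_qkv(x)
        branches = []
        for agg in self.multiscale_aggregate(qkv):
            tokens = agg.reshape(b, 3 * c, h * w).transpose((0, 2, 1))   # (B, N, 3C)
            q = tokens[:, :, 0:c]
            k = tokens[:, :, c:2 * c]
            v = tokens[:, :, 2 * c:3 * c]
            att = relu_linear_attention(
                q, k, v, epsilon=self.cfg.epsilon,
                normalized=not self.cfg.unnormalized_attention)
            branches.append(att.transpose((0, 2, 1)).reshape(b, c, h, w))
        merged = concatenate(branches, axis=1)
        o = self.out_proj(merged) + x
        y = self.mlp(self.norm(o)) + o
        return y

    def zero_output_projections(self) -> None:
        """Kill both residual paths: the block becomes the identity map."""
        self.out_proj.weight.data[:] = 0
        self.out_proj.bias.data[:] = 0
        self.mlp._order[-1].weight.data[:] = 0
        self.mlp._order[-1].bias.data[:] = 0
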