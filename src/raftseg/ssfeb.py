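"""Spatial-spectral feature extraction block (SSFEB).

The block fuses two branches with the input through an element-wise sum::

    F_G(x) = K_spa(x) + K_spe(x) + x

*Spectral branch* (``SpectralBranch``): the feature map is permuted so
that the original **width** axis becomes the grouping ("channel") axis
and depthwise kernels slide over the (height x original-channel) plane.
The permuted map is split into three equal groups along the grouping
axis; each group passes through a depthwise convolution of its own
geometry (3x3 for local spectral neighbourhoods, 1xk and kx1 with k=11
for long-range spectral correlation), the groups are concatenated back,
normalized (BatchNorm) and passed through a two-layer 1x1 perceptron,
then the permutation is inverted.  Because the depthwise filter count in
this branch equals the spatial width of the map, the block is built for
one fixed tile size.

*Spatial branch* (``SpatialBranch``): a 1x1 bottleneck projection
(channels / reduction), a depthwise 3x3, and a 1x1 expansion back to the
input channel count.

Both branches preserve the input extents exactly, which the residual sum
requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Tensor, Module, Conv2d, BatchNorm2d, GELU, Sequential, concatenate,
)

__all__ = ["SSFEBConfig", "SSFEB", "SpectralBranch", "SpatialBranch",
           "permute_spectral", "split_groups"]


@dataclass
class SSFEBConfig:
    """Hyperparameters of one SSFEB.

    ``width`` is the spatial width of the feature map the block will see;
    the spectral branch's depthwise filters are allocated per width
    column, so it must be fixed at build time.
    """

    channels: int
    width: int
    spectral_kernel: int = 11
    split_count: int = 3
    spatial_reduction: int = 4
    mlp_expansion: int = 4

    def validate(self) -> None:
        if self.channels < 1:
            raise ValueError(f"channels must be positive, got {self.channels}")
        if self.width < 1:
            raise ValueError(f"width must be positive, got {self.width}")
        if self.spectral_kernel % 2 == 0 or self.spectral_kernel < 1:
            raise ValueError(f"spectral_kernel must be odd and positive, got {self.spectral_kernel}")
        if self.split_count < 1:
            raise ValueError(f"split_count must be positive, got {self.split_count}")
        if self.spatial_reduction < 1 or self.channels % self.spatial_reduction:
            raise ValueError(
                f"channels ({self.channels}) must be divisible by spatial_reduction "
                f"({self.spatial_reduction})")
        if self.mlp_expansion < 1:
            raise ValueError(f"mlp_expansion must be positive, got {self.mlp_expansion}")


def permute_spectral(x):
    """Exchange the channel and width axes: (B, C, H, W) -> (B, W, H, C).

    The original width becomes the grouping axis and subsequent depthwise
    kernels act on the (height x original-channels) plane.  The transform
    is its own inverse (the axis permutation (0, 3, 2, 1) is an
    involution), so applying it twice restores the input bit-exactly.
    """
    if isinstance(x, Tensor):
        return x.transpose((0, 3, 2, 1))
    return np.transpose(x, (0, 3, 2, 1))


def split_groups(xp, n: int, pad: bool = False):
    """Split a permuted map into ``n`` equal pieces along the grouping axis.

    Returns ``(pieces, n_padded_columns)``.  With ``pad=False`` a
    non-divisible extent raises; with ``pad=True`` the axis is zero-padded
    up to the next multiple of ``n`` and the number of appended columns is
    returned so callers can crop them after fusion.
    """
    if n < 1:
        raise ValueError(f"split count must be >= 1, got {n}")
    extent = xp.shape[1]
    rem = extent % n
    padding = 0 if rem == 0 else n - rem
    if padding and not pad:
        raise ValueError(
            f"grouping axis extent {extent} is not divisible by {n} groups "
            "and padding is disabled")
    if padding:
        if isinstance(xp, Tensor):
            xp = xp.pad_axis(1, 0, padding)
        else:
            widths = [(0, 0)] * xp.ndim
            widths[1] = (0, padding)
            xp = np.pad(xp, widths)
    size = xp.shape[1] // n
    pieces = []
    for i in range(n):
        sl = (slice(None), slice(i * size, (i + 1) * size))
        pieces.append(xp[sl])
    return pieces, padding


class SpectralBranch(Module):
    """K_spe: permuted depthwise convolutions + BatchNorm + 1x1 MLP."""

    def __init__(self, cfg: SSFEBConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        n = cfg.split_count
        k = cfg.spectral_kernel
        w = cfg.width
        self.padded_width = w if w % n == 0 else w + (n - w % n)
        gw = self.padded_width // n
        # one depthwise geometry per group, in the listed order 3x3 / 1xk / kx1
        kernel_shapes = [(3, 3), (1, k), (k, 1)]
        if n != 3:
            # generalize: cycle the three geometries over the groups
            kernel_shapes = [kernel_shapes[i % 3] for i in range(n)]
        self.group_convs = Sequential(*[
            Conv2d(gw, gw, ks, padding=(ks[0] // 2, ks[1] // 2), groups=gw, rng=rng)
            for ks in kernel_shapes
        ])
        self.norm = BatchNorm2d(self.padded_width)
        e = cfg.mlp_expansion
        self.mlp = Sequential(
            Conv2d(self.padded_width, e * self.padded_width, 1, rng=rng),
            GELU(),
            Conv2d(e * self.padded_width, self.padded_width, 1, rng=rng),
        )

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[3] != self.cfg.width:
            raise ValueError(
                f"spectral branch was built for width {self.cfg.width}, got {x.shape[3]}")
        xp = permute_spectral(x)
        pieces, padding = split_groups(xp, self.cfg.split_count, pad=True)
        outs = [conv(piece) for conv, piece in zip(self.group_convs, pieces)]
        y = concatenate(outs, axis=1)
        y = self.norm(y)
        y = self.mlp(y)
        if padding:
            y = y[:, : self.cfg.width]
        return permute_spectral(y)


class SpatialBranch(Module):
    """K_spa: 1x1 reduce -> depthwise 3x3 -> 1x1 restore."""

    def __init__(self, cfg: SSFEBConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        c, r = cfg.channels, cfg.spatial_reduction
        mid = c // r
        self.reduce = Conv2d(c, mid, 1, rng=rng)
        self.depthwise = Conv2d(mid, mid, 3, padding=1, groups=mid, rng=rng)
        self.restore = Conv2d(mid, c, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.restore(self.depthwise(self.reduce(x)))


class SSFEB(Module):
    """Triple-residual fusion of the spectral and spatial branches."""

    def __init__(self, cfg: SSFEBConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.spectral = SpectralBranch(cfg, rng)
        self.spatial = SpatialBranch(cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.spatial(x) + self.spectral(x) + x

    def zero_output_projections(self) -> None:
        """Kill both branches: the block becomes the identity map."""
        self.spectral.mlp._order[-1].weight.data[:] = 0
        self.spectral.mlp._order[-1].bias.data[:] = 0
        self.spatial.restore.weight.data[:] = 0
        self.spatial.restore.bias.data[:] = 0
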