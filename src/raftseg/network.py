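"""MSSFNet: encoder-decoder segmentation network for 10-band tiles.

Encoder: a ResNet18-shaped stem (7x7 stride-2 convolution, BatchNorm,
ReLU, 3x3 stride-2 max pool) followed by four stages of SSFEBs (two per
stage by default) with stride-2 1x1 projection convolutions between
stages.  The MSAB sits on the deepest (1/32-resolution) map.

Decoder: four levels of 2x bilinear upsampling, skip concatenation
(stage 3, stage 2, stage 1 and the stem convolution map) and two
3x3 conv + BatchNorm + ReLU layers each, then a parameter-free 2x
upsample back to the input resolution, a 1x1 convolution and a sigmoid,
yielding a single-channel raft-probability map.

Because the SSFEB spectral branch allocates depthwise filters per width
column, the network is built for one fixed tile size and rejects other
input extents at forward time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Tensor, Module, Conv2d, BatchNorm2d, ReLU, Sigmoid, MaxPool2d,
    Sequential, concatenate, upsample_bilinear2x,
)
from .ssfeb import SSFEB, SSFEBConfig
from .msab import MSAB, AttentionConfig

__all__ = ["NetworkConfig", "MSSFNet", "build_model", "count_parameters"]


@dataclass
class NetworkConfig:
    in_bands: int = 10
    stage_widths: tuple = (64, 128, 256, 512)
    blocks_per_stage: int = 2
    tile_size: int = 512
    decoder_widths: tuple = (256, 128, 64, 32)
    width_multiplier: float = 1.0
    spectral_kernel: int = 11
    spatial_reduction: int = 4
    attention_scales: tuple = (3, 5)

    def validate(self) -> None:
        if self.in_bands < 1:
            raise ValueError(f"invalid config field in_bands: {self.in_bands}")
        if self.tile_size % 32:
            raise ValueError(
                f"invalid config field tile_size: {self.tile_size} (must be divisible by 32)")
        if len(self.stage_widths) != 4 or list(self.stage_widths) != sorted(set(self.stage_widths)):
            raise ValueError(
                f"invalid config field stage_widths: {self.stage_widths} "
                "(need 4 strictly increasing values)")
        if len(self.decoder_widths) != 4:
            raise ValueError(f"invalid config field decoder_widths: {self.decoder_widths}")
        if self.blocks_per_stage < 1:
            raise ValueError(f"invalid config field blocks_per_stage: {self.blocks_per_stage}")
        if self.width_multiplier <= 0:
            raise ValueError(f"invalid config field width_multiplier: {self.width_multiplier}")
        for w in self.scaled_stage_widths() + self.scaled_decoder_widths():
            if w < 1:
                raise ValueError(
                    f"invalid config field width_multiplier: {self.width_multiplier} "
                    "(a scaled width collapsed below 1)")
        for w in self.scaled_stage_widths():
            if w % self.spatial_reduction:
                raise ValueError(
                    f"invalid config field spatial_reduction: {self.spatial_reduction} "
                    f"(scaled stage width {w} not divisible)")

    def scaled_stage_widths(self) -> list:
        return [max(1, int(round(w * self.width_multiplier))) for w in self.stage_widths]

    def scaled_decoder_widths(self) -> list:
        return [max(1, int(round(w * self.width_multiplier))) for w in self.decoder_widths]

    def to_dict(self) -> dict:
        return {
            "in_bands": self.in_bands,
            "stage_widths": list(self.stage_widths),
            "blocks_per_stage": self.blocks_per_stage,
            "tile_size": self.tile_size,
            "decoder_widths": list(self.decoder_widths),
            "width_multiplier": self.width_multiplier,
            "spectral_kernel": self.spectral_kernel,
            "spatial_reduction": self.spatial_reduction,
            "attention_scales": list(self.attention_scales),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for key in ("stage_widths", "decoder_widths", "attention_scales"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _conv_bn_relu(cin: int, cout: int, rng) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, 3, padding=1, rng=rng),
        BatchNorm2d(cout),
        ReLU(),
    )


class _DecoderLevel(Module):
    def __init__(self, cin: int, skip: int, cout: int, rng):
        super().__init__()
        self.block = Sequential(
            _conv_bn_relu(cin + skip, cout, rng),
            _conv_bn_relu(cout, cout, rng),
        )

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x = upsample_bilinear2x(x)
        x = concatenate([x, skip], axis=1)
        return self.block(x)


class MSSFNet(Module):
    """The assembled segmentation model."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        widths = cfg.scaled_stage_widths()
        dwidths = cfg.scaled_decoder_widths()
        t = cfg.tile_size

        self.stem_conv = Conv2d(cfg.in_bands, widths[0], 7, stride=2, padding=3, rng=rng)
        self.stem_norm = BatchNorm2d(widths[0])
        self.stem_act = ReLU()
        self.stem_pool = MaxPool2d(3, 2, 1)

        stage_res = [t // 4, t // 8, t // 16, t // 32]
        stages = []
        downs = []
        for i, w in enumerate(widths):
            blocks = [
                SSFEB(SSFEBConfig(
                    channels=w, width=stage_res[i],
                    spectral_kernel=cfg.spectral_kernel,
                    spatial_reduction=cfg.spatial_reduction), rng=rng)
                for _ in range(cfg.blocks_per_stage)
            ]
            stages.append(Sequential(*blocks))
            if i < 3:
                downs.append(Conv2d(widths[i], widths[i + 1], 1, stride=2, rng=rng))
        self.stage1, self.stage2, self.stage3, self.stage4 = stages
        self.down1, self.down2, self.down3 = downs

        self.attention = MSAB(AttentionConfig(
            channels=widths[3], scales=cfg.attention_scales), rng=rng)

        self.dec1 = _DecoderLevel(widths[3], widths[2], dwidths[0], rng)
        self.dec2 = _DecoderLevel(dwidths[0], widths[1], dwidths[1], rng)
        self.dec3 = _DecoderLevel(dwidths[1], widths[0], dwidths[2], rng)
        self.dec4 = _DecoderLevel(dwidths[2], widths[0], dwidths[3], rng)
        self.head = Conv2d(dwidths[3], 1, 1, rng=rng)
        self.head_act = Sigmoid()

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        b, c, h, w = x.shape
        t = self.cfg.tile_size
        if c != self.cfg.in_bands:
            raise ValueError(f"expected {self.cfg.in_bands} bands, got {c}")
        if h != t or w != t:
            raise ValueError(
                f"model is built for {t}x{t} tiles (the spectral branch fixes "
                f"the width per stage); got {h}x{w}")
        s0 = self.stem_act(self.stem_norm(self.stem_conv(x)))   # 1/2
        e1 = self.stage1(self.stem_pool(s0))                    # 1/4
        e2 = self.stage2(self.down1(e1))                        # 1/8
        e3 = self.stage3(self.down2(e2))                        # 1/16
        e4 = self.stage4(self.down3(e3))                        # 1/32
        bott = self.attention(e4)
        d = self.dec1(bott, e3)
        d = self.dec2(d, e2)
        d = self.dec3(d, e1)
        d = self.dec4(d, s0)
        d = upsample_bilinear2x(d)
        return self.head_act(self.head(d))

    def predict(self, x) -> np.ndarray:
        """Eval-mode probability map as a numpy array."""
        was_training = self.training
        self.eval()
        out = self.forward(x).data
        if was_training:
            self.train()
        return out


def build_model(cfg: NetworkConfig, seed: int) -> MSSFNet:
    """Build an MSSFNet with deterministic seeded initialization."""
    return MSSFNet(cfg, seed=seed)


def count_parameters(model: Module) -> int:
    """Total scalar trainable parameter count."""
    return int(sum(p.data.size for p in model.parameters()))
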