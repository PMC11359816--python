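"""Training objective: equally weighted binary cross-entropy + Dice loss."""

from __future__ import annotations

import numpy as np

from .nn import Tensor

__all__ = ["bce_loss", "dice_loss", "combined_loss", "PROB_CLAMP"]

PROB_CLAMP = 1e-7


def _lift_pair(pred, target):
    p = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, dtype=float))
    t = target if isinstance(target, Tensor) else Tensor(np.asarray(target, dtype=float))
    if p.shape != t.shape:
        raise ValueError(f"prediction shape {p.shape} != target shape {t.shape}")
    return p, t


def bce_loss(pred, target) -> Tensor:
    """Mean binary cross-entropy; probabilities clamped to [1e-7, 1 - 1e-7]."""
    p, t = _lift_pair(pred, target)
    p = p.clip(PROB_CLAMP, 1.0 - PROB_CLAMP)
    return -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()


def dice_loss(pred, target, smooth: float = 1.0) -> Tensor:
    """1 minus the (smoothed) Dice overlap 2|P.Y| / (|P| + |Y|)."""
    p, t = _lift_pair(pred, target)
    inter = (p * t).sum()
    return 1.0 - (2.0 * inter + smooth) / (p.sum() + t.sum() + smooth)


def combined_loss(pred, target, smooth: float = 1.0) -> Tensor:
    """0.5 * BCE + 0.5 * Dice."""
    p, t = _lift_pair(pred, target)
    return 0.5 * bce_loss(p, t) + 0.5 * dice_loss(p, t, smooth=smooth)
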