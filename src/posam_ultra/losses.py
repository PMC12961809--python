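"""Segmentation losses: binary cross-entropy, soft Dice, focal, their
weighted composite, and the deeply-supervised total.

All functions accept autograd Tensors or plain arrays and return a scalar
Tensor, so the same code path serves training and direct evaluation
(``float(loss)`` gives the value).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor
from .types import LossWeights

__all__ = [
    "bce_loss",
    "dice_loss",
    "focal_loss",
    "composite_loss",
    "total_loss",
]

_EPS = 1e-7


def _pair(s, g) -> tuple[Tensor, Tensor]:
    s, g = as_tensor(s), as_tensor(g)
    if s.shape != g.shape:
        raise ValueError(f"prediction shape {s.shape} != target shape {g.shape}")
    return s, g


def bce_loss(s, g) -> Tensor:
    """Mean binary cross-entropy, predictions clamped to [1e-7, 1 - 1e-7]."""
    s, g = _pair(s, g)
    sc = s.clip(_EPS, 1.0 - _EPS)
    return -(g * sc.log() + (1.0 - g) * (1.0 - sc).log()).mean()


def dice_loss(s, g, smooth: float = 1.0) -> Tensor:
    """1 - (2*sum(S*G) + smooth) / (sum(S) + sum(G) + smooth)."""
    s, g = _pair(s, g)
    num = 2.0 * (s * g).sum() + smooth
    den = s.sum() + g.sum() + smooth
    return 1.0 - num / den


def focal_loss(s, g, gamma: float = 2.0, alpha: float = 0.25) -> Tensor:
    """Mean of ``-alpha_t * (1 - p_t)^gamma * log(p_t)`` where ``p_t`` is the
    predicted probability of the true class."""
    if gamma < 0:
        raise ValueError("focal gamma must be >= 0")
    s, g = _pair(s, g)
    sc = s.clip(_EPS, 1.0 - _EPS)
    p_t = sc * g + (1.0 - sc) * (1.0 - g)
    alpha_t = alpha * g + (1.0 - alpha) * (1.0 - g)
    return -(alpha_t * (1.0 - p_t) ** gamma * p_t.log()).mean()


def composite_loss(s, g, weights: LossWeights) -> Tensor:
    """``w_bce * BCE + w_dice * Dice + w_focal * Focal``."""
    total = as_tensor(0.0)
    if weights.w_bce:
        total = total + weights.w_bce * bce_loss(s, g)
    if weights.w_dice:
        total = total + weights.w_dice * dice_loss(s, g)
    if weights.w_focal:
        total = total + weights.w_focal * focal_loss(
            s, g, gamma=weights.focal_gamma, alpha=weights.focal_alpha)
    return total


def total_loss(main_loss, aux1_loss, aux2_loss, lambda1: float, lambda2: float
               ) -> Tensor:
    """Deep-supervision total: ``L_main + lambda1 * L_aux1 + lambda2 * L_aux2``."""
    for v in (lambda1, lambda2):
        if not np.isfinite(v):
            raise ValueError("lambda weights must be finite")
    return as_tensor(main_loss) + lambda1 * as_tensor(aux1_loss) \
        + lambda2 * as_tensor(aux2_loss)
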