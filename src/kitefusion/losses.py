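"""Compound Dice + cross-entropy segmentation loss.

The loss is the alpha-weighted sum of a per-batch-averaged soft Dice loss and
a cross-entropy term, computed on per-pixel class *probabilities* ``s`` and
one-hot references ``r``::

    L = alpha * L_CE + (1 - alpha) * L_Dice

    L_Dice = (1/C) sum_c [ 1 - 2 (sum_{i,k} r s + eps) / (sum_{i,k} (r + s) + eps) ]

where ``c`` indexes the images of a batch (C of them), ``i`` the pixels and
``k`` the two classes.  The cross-entropy term supports two normalizations:

- ``per_pixel_mean`` (default): -(1/(C*N)) sum r log s, which keeps the CE
  term on the same O(1) scale as the Dice term;
- ``paper_sum``: -(1/C) sum_c sum_{i,k} r log s, i.e. summed over pixels and
  divided only by the batch size (N times larger for an N-pixel image).

All functions accept either NumPy arrays or autodiff :class:`~kitefusion.nn.Tensor`
inputs with layout ``(batch, classes, *spatial)``; with tensors the returned
scalar participates in backprop, which is how the training loops use it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["LossConfig", "dice_loss", "ce_loss", "dice_ce"]

LOG_CLAMP = 1e-12


@dataclass
class LossConfig:
    """Weights and stabilizers of the compound loss.

    alpha: weight of the cross-entropy term (the Dice term gets 1 - alpha).
    epsilon: additive stabilizer in the Dice ratio.
    ce_reduction: 'per_pixel_mean' or 'paper_sum' (see module docstring).
    """

    alpha: float = 0.5
    epsilon: float = 1e-5
    ce_reduction: str = "per_pixel_mean"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.ce_reduction not in ("per_pixel_mean", "paper_sum"):
            raise ValueError(f"unknown ce_reduction {self.ce_reduction!r}")


def _flatten(x, as_tensor):
    """Reshape (C, K, *spatial) -> (C, K*N) keeping the batch axis first."""
    c = x.shape[0]
    if as_tensor:
        return Tensor.as_tensor(x).reshape(c, -1)
    return np.asarray(x, dtype=np.float64).reshape(c, -1)


def _check(s, r):
    if s.shape != r.shape:
        raise ValueError(f"shape mismatch: s {s.shape} vs r {r.shape}")
    if s.shape[0] == 0:
        raise ValueError("empty batch")


def dice_loss(s, r, epsilon: float = 1e-5):
    """Soft Dice loss averaged over the batch; near 0 for a perfect prediction,
    0.5 for a uniform two-class prediction."""
    _check(s, r)
    is_t = isinstance(s, Tensor) or isinstance(r, Tensor)
    sf, rf = _flatten(s, is_t), _flatten(r, is_t)
    inter = (rf * sf).sum(axis=1)
    total = (rf + sf).sum(axis=1)
    per_image = 1.0 - (inter + epsilon) * 2.0 / (total + epsilon)
    return per_image.mean() if is_t else float(np.mean(per_image))


def ce_loss(s, r, reduction: str = "per_pixel_mean"):
    """Cross entropy of probabilities against one-hot references (>= 0)."""
    _check(s, r)
    if reduction not in ("per_pixel_mean", "paper_sum"):
        raise ValueError(f"unknown ce_reduction {reduction!r}")
    is_t = isinstance(s, Tensor) or isinstance(r, Tensor)
    sf, rf = _flatten(s, is_t), _flatten(r, is_t)
    c = sf.shape[0]
    n_pixels = sf.shape[1] // s.shape[1]  # per-image pixel count
    if is_t:
        total = -(rf * sf.clamp_min(LOG_CLAMP).log()).sum()
    else:
        total = -np.sum(rf * np.log(np.maximum(sf, LOG_CLAMP)))
    denom = c * n_pixels if reduction == "per_pixel_mean" else c
    out = total * (1.0 / denom)
    return out if is_t else float(out)


def dice_ce(s, r, config: LossConfig | None = None):
    """The alpha-convex combination of cross-entropy and Dice losses."""
    cfg = config or LossConfig()
    ce = ce_loss(s, r, reduction=cfg.ce_reduction)
    dl = dice_loss(s, r, epsilon=cfg.epsilon)
    return cfg.alpha * ce + (1.0 - cfg.alpha) * dl
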