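"""Hybrid training objective: binary cross-entropy plus soft Dice.

L_total = L_BCE + L_Dice with equal weighting and no tunable trade-off.
BCE is the mean over all pixels of -[t log p + (1-t) log(1-p)] with
predictions clamped to [eps, 1-eps]. The Dice term is the soft (probability,
not thresholded) formulation 1 - (2*sum(p t) + s) / (sum p + sum t + s) with
smoothing constant s = 1, computed per image and averaged over the batch so
it matches the per-image structure of the evaluation means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import DimensionError

__all__ = ["LossValues", "bce_loss", "dice_loss", "hybrid_loss", "BCE_EPS"]

BCE_EPS = 1e-7


@dataclass
class LossValues:
    bce: Tensor
    dice: Tensor
    total: Tensor

    def as_floats(self) -> dict[str, float]:
        return {"bce": self.bce.item(), "dice": self.dice.item(),
                "total": self.total.item()}


def _check_pair(pred: Tensor, target: Tensor, validate_binary: bool) -> None:
    if pred.shape != target.shape:
        raise DimensionError(
            f"prediction shape {pred.shape} != target shape {target.shape}")
    if validate_binary:
        t = target.data
        if not np.all((t == 0) | (t == 1)):
            raise ValueError("target mask must contain only 0/1 values")


def bce_loss(pred, target) -> Tensor:
    """Mean binary cross-entropy over all pixels."""
    pred, target = ad.astensor(pred), ad.astensor(target)
    _check_pair(pred, target, validate_binary=True)
    p = ad.clip(pred, BCE_EPS, 1.0 - BCE_EPS)
    t = target.data
    ll = Tensor(t) * ad.log(p) + Tensor(1.0 - t) * ad.log(1.0 - p)
    return -ll.mean()


def dice_loss(pred, target, smooth: float = 1.0) -> Tensor:
    """Soft Dice loss, per image then averaged over the batch.

    Inputs of shape (N, ...) are treated as N images; lower-rank inputs as a
    single image.
    """
    pred, target = ad.astensor(pred), ad.astensor(target)
    _check_pair(pred, target, validate_binary=False)
    if pred.ndim < 2:
        p = pred.reshape((1, -1))
        t = target.reshape((1, -1))
    else:
        n = pred.shape[0]
        p = pred.reshape((n, -1))
        t = target.reshape((n, -1))
    inter = (p * t).sum(axis=1)
    denom = p.sum(axis=1) + t.sum(axis=1)
    dice = (2.0 * inter + smooth) / (denom + smooth)
    return (1.0 - dice).mean()


def hybrid_loss(pred, target) -> LossValues:
    """Equal-weight sum of BCE and soft Dice; components kept for logging."""
    bce = bce_loss(pred, target)
    dice = dice_loss(pred, target)
    return LossValues(bce=bce, dice=dice, total=bce + dice)
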