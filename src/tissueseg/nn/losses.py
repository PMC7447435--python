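"""Training losses for boundary prediction: BCE, Dice, and their blend.

The combined loss is ``α·L_BCE + β_loss·L_Dice`` (both weights 1 by
default).  BCE is the mean voxel-wise binary cross-entropy; the Dice loss
is ``1 − (2·Σ p·t + ε) / (Σ p + Σ t + ε)`` with a small smoothing ε so
empty targets are handled.  During training the loss is evaluated on
logits for numerical stability; the public :func:`bce_dice_loss` takes
post-sigmoid probabilities, matching how predictions are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import sigmoid

__all__ = ["LossConfig", "bce_dice_loss", "loss_and_grad_from_logits"]

_DICE_EPS = 1e-6


@dataclass(frozen=True)
class LossConfig:
    """Loss selection: ``kind`` ∈ {bce, dice, bce_dice}; ``alpha`` and
    ``beta_loss`` are the BCE and Dice mixing weights (this β is the loss
    weight, unrelated to the graph-partitioning bias)."""

    kind: str = "bce_dice"
    alpha: float = 1.0
    beta_loss: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("bce", "dice", "bce_dice"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.alpha < 0 or self.beta_loss < 0:
            raise ValueError("loss weights must be >= 0")
        if self.kind == "bce_dice" and self.alpha == 0 and self.beta_loss == 0:
            raise ValueError("alpha and beta_loss cannot both be 0")

    @property
    def effective_weights(self) -> tuple[float, float]:
        if self.kind == "bce":
            return self.alpha if self.alpha > 0 else 1.0, 0.0
        if self.kind == "dice":
            return 0.0, self.beta_loss if self.beta_loss > 0 else 1.0
        return self.alpha, self.beta_loss


def _dice_loss(p: np.ndarray, t: np.ndarray) -> float:
    num = 2.0 * float((p * t).sum()) + _DICE_EPS
    den = float(p.sum()) + float(t.sum()) + _DICE_EPS
    return 1.0 - num / den


def bce_dice_loss(pred: np.ndarray, target: np.ndarray, cfg: LossConfig | None = None) -> float:
    """Combined loss on post-sigmoid probabilities ``pred`` ∈ (0, 1).

    Non-negative; approaches 0 as the prediction approaches a binary target.
    """
    cfg = cfg or LossConfig()
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    a, b = cfg.effective_weights
    p = np.clip(pred, 1e-12, 1.0 - 1e-12)
    loss = 0.0
    if a > 0:
        loss += a * float(-(target * np.log(p) + (1 - target) * np.log(1 - p)).mean())
    if b > 0:
        loss += b * _dice_loss(pred, target)
    return loss


def loss_and_grad_from_logits(
    logits: np.ndarray, target: np.ndarray, cfg: LossConfig | None = None
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient w.r.t. the logits (numerically stable).

    BCE on logits: ``max(z,0) − z·t + log(1+exp(−|z|))`` with gradient
    ``(σ(z) − t)/n``; the Dice term is differentiated through the sigmoid.
    """
    cfg = cfg or LossConfig()
    z = np.asarray(logits, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if z.shape != t.shape:
        raise ValueError("logits/target shape mismatch")
    a, b = cfg.effective_weights
    p = sigmoid(z)
    n = z.size
    loss = 0.0
    grad = np.zeros_like(z)
    if a > 0:
        bce = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
        loss += a * float(bce.mean())
        grad += a * (p - t) / n
    if b > 0:
        num = 2.0 * float((p * t).sum()) + _DICE_EPS
        den = float(p.sum()) + float(t.sum()) + _DICE_EPS
        loss += b * (1.0 - num / den)
        ddice_dp = -(2.0 * t * den - num) / den**2
        grad += b * ddice_dp * p * (1.0 - p)
    return loss, grad
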