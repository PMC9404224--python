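"""Segmentation training objective: equally weighted soft Dice + cross-entropy.

The network emits raw two-class scores; cross-entropy is the mean over
voxels of the negative log softmax probability of the true class, and the
Dice term is the soft Dice of the foreground-channel probability against
the binary target, pooled over the whole batch, with a small smoothing term
guarding empty-target patches. The combined loss is

    loss = dice_weight * dice_loss + ce_weight * cross_entropy_loss

with both weights 0.5 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "softmax",
    "dice_loss",
    "cross_entropy_loss",
    "combined_loss",
    "combined_loss_with_grad",
]


@dataclass(frozen=True)
class LossConfig:
    dice_weight: float = 0.5
    ce_weight: float = 0.5
    smooth_term: float = 1e-5

    def __post_init__(self):
        if self.dice_weight < 0 or self.ce_weight < 0:
            raise ValueError("loss weights must be non-negative")


def softmax(scores: np.ndarray, axis: int = 1) -> np.ndarray:
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _check_shapes(probs_or_scores: np.ndarray, target: np.ndarray) -> None:
    if probs_or_scores.shape[0] != target.shape[0] or probs_or_scores.shape[2:] != target.shape[1:]:
        raise ValueError(
            f"shape mismatch: scores {probs_or_scores.shape} vs target {target.shape}"
        )


def _dice_terms(probs: np.ndarray, target: np.ndarray, smooth: float):
    p_fg = probs[:, 1]
    y = target.astype(np.float64)
    inter = float((p_fg * y).sum())
    s_p, s_y = float(p_fg.sum()), float(y.sum())
    denom = s_p + s_y + smooth
    return p_fg, y, inter, denom


def dice_loss(probs: np.ndarray, target: np.ndarray, cfg: LossConfig | None = None) -> float:
    """Soft Dice loss ``1 - (2 sum(p*y) + s) / (sum(p) + sum(y) + s)``.

    ``probs`` must be softmax-normalized class probabilities ``(N, 2, ...)``
    and ``target`` a binary mask ``(N, ...)``. Computed on the foreground
    channel, pooled over the batch. Range [0, 1].
    """
    cfg = cfg or LossConfig()
    _check_shapes(probs, target)
    _, _, inter, denom = _dice_terms(probs, target, cfg.smooth_term)
    return float(1.0 - (2.0 * inter + cfg.smooth_term) / denom)


def cross_entropy_loss(scores: np.ndarray, target: np.ndarray) -> float:
    """Mean over voxels of -log softmax probability of the true class."""
    _check_shapes(scores, target)
    probs = softmax(scores)
    n = target.size
    idx = target.astype(np.int64)
    p_true = np.take_along_axis(probs, idx[:, None], axis=1)[:, 0]
    return float(-np.log(np.clip(p_true, 1e-12, None)).sum() / n)


def combined_loss(
    scores: np.ndarray, target: np.ndarray, cfg: LossConfig | None = None
) -> float:
    cfg = cfg or LossConfig()
    probs = softmax(scores)
    return cfg.dice_weight * dice_loss(probs, target, cfg) + cfg.ce_weight * cross_entropy_loss(
        scores, target
    )


def combined_loss_with_grad(
    scores: np.ndarray, target: np.ndarray, cfg: LossConfig | None = None
) -> tuple[float, np.ndarray, dict[str, float]]:
    """Loss value, gradient w.r.t. the raw scores, and the two components."""
    cfg = cfg or LossConfig()
    _check_shapes(scores, target)
    probs = softmax(scores)
    n = target.size
    idx = target.astype(np.int64)

    # cross-entropy and its gradient through the softmax
    p_true = np.take_along_axis(probs, idx[:, None], axis=1)[:, 0]
    ce = float(-np.log(np.clip(p_true, 1e-12, None)).sum() / n)
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, idx[:, None], 1.0, axis=1)
    dce = (probs - onehot) / n

    # soft Dice on the foreground channel, batch-pooled
    p_fg, y, inter, denom = _dice_terms(probs, target, cfg.smooth_term)
    dice = float(1.0 - (2.0 * inter + cfg.smooth_term) / denom)
    # d(dice)/d(p_fg), then through the softmax Jacobian
    g_fg = -(2.0 * y * denom - (2.0 * inter + cfg.smooth_term)) / denom**2
    gp = g_fg * probs[:, 1]
    ddice = np.empty_like(probs)
    ddice[:, 1] = probs[:, 1] * g_fg - probs[:, 1] * gp
    ddice[:, 0] = -probs[:, 0] * gp

    loss = cfg.dice_weight * dice + cfg.ce_weight * ce
    grad = (cfg.dice_weight * ddice + cfg.ce_weight * dce).astype(np.float32)
    return loss, grad, {"dice_loss": dice, "ce_loss": ce}
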