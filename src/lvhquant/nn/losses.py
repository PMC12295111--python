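"""Loss functions returning (loss, gradient-wrt-input) pairs."""

from __future__ import annotations

import numpy as np


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over a batch of logits (N, C); labels are ints.

    Returns ``(loss, dlogits)`` with the softmax folded into the gradient.
    """
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def dice_loss_grad(probs: np.ndarray, target: np.ndarray, eps: float = 1.0):
    """Soft-Dice loss on the foreground channel of per-pixel probabilities.

    ``probs`` is (N, 2, H, W) after a pixelwise softmax, ``target`` a
    binary (N, H, W) myocardium mask. Loss is ``1 - soft Dice`` with sums
    pooled over the whole batch; returns ``(loss, dprobs)``.
    """
    p = probs[:, 1]
    g = target.astype(float)
    inter = (p * g).sum()
    denom = p.sum() + g.sum()
    a = 2.0 * inter + eps
    b = denom + eps
    loss = float(1.0 - a / b)
    dp = (a - 2.0 * g * b) / (b * b)
    grad = np.zeros_like(probs)
    grad[:, 1] = dp
    return loss, grad


def soft_dice(probs: np.ndarray, target: np.ndarray, eps: float = 1.0) -> float:
    """Soft Dice coefficient in [0, 1] (not a loss)."""
    p = probs[:, 1]
    g = target.astype(float)
    return float((2.0 * (p * g).sum() + eps) / (p.sum() + g.sum() + eps))
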