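"""Dice overlap metric and the combined dice + focal training objective.

Evaluation uses the hard dice score 2|G∩P| / (|G|+|P|) per foreground class
after binarizing sigmoid outputs at 0.5, macro-averaged over the two
classes. Training uses a soft-dice term plus a focal cross-entropy term
α(1-p_t)^γ (-log p_t) with the standard p_t convention (p_t = P where the
ground truth is 1, 1-P where it is 0); α = 0.25 and γ = 2 by default. The
focal factor down-weights pixels the model already classifies confidently,
concentrating gradient on the hard boundary pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_types import FOREGROUND_CLASSES

_CLIP = 1e-7


@dataclass(frozen=True)
class DiceReport:
    """Per-class dice values plus their macro average."""

    per_class: dict[str, float]
    macro: float
    threshold: float = 0.5

    def __post_init__(self) -> None:
        for name, v in self.per_class.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"dice for {name!r} outside [0, 1]: {v}")


def dice_score(
    pred: np.ndarray,
    true_mask: np.ndarray,
    threshold: float = 0.5,
    class_names: tuple[str, ...] = FOREGROUND_CLASSES,
) -> DiceReport:
    """Hard dice per foreground class, macro-averaged.

    ``pred`` holds probabilities (or already-binary values) shaped
    C x H x W or N x C x H x W; ``true_mask`` is binary with the same
    shape. Probabilities are binarized at ``threshold``. A class empty in
    both prediction and ground truth scores 1 (empty-vs-empty is a perfect
    prediction).
    """
    pred = np.asarray(pred, dtype=np.float64)
    true_mask = np.asarray(true_mask)
    if pred.shape != true_mask.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs mask {true_mask.shape}")
    if not np.isin(true_mask, (0, 1)).all():
        raise ValueError("true mask must be binary")
    if pred.ndim == 3:
        pred = pred[None]
        true_mask = true_mask[None]
    if pred.ndim != 4:
        raise ValueError(f"expected C x H x W or N x C x H x W, got {pred.shape}")
    if pred.shape[1] != len(class_names):
        raise ValueError(f"{pred.shape[1]} channels but {len(class_names)} class names")

    hard = (pred >= threshold).astype(np.float64)
    g = true_mask.astype(np.float64)
    per_class: dict[str, float] = {}
    for c, name in enumerate(class_names):
        p_c, g_c = hard[:, c], g[:, c]
        inter = float((p_c * g_c).sum())
        denom = float(p_c.sum() + g_c.sum())
        per_class[name] = 1.0 if denom == 0 else 2.0 * inter / denom
    macro = float(np.mean(list(per_class.values())))
    return DiceReport(per_class=per_class, macro=macro, threshold=threshold)


def soft_dice_loss(pred: np.ndarray, true_mask: np.ndarray) -> float:
    """1 - soft dice, averaged over channels; pred stays un-thresholded."""
    pred = np.asarray(pred, dtype=np.float64)
    g = np.asarray(true_mask, dtype=np.float64)
    if pred.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs mask {g.shape}")
    if pred.ndim == 3:
        pred, g = pred[None], g[None]
    losses = []
    for c in range(pred.shape[1]):
        p_c, g_c = pred[:, c], g[:, c]
        denom = p_c.sum() + g_c.sum()
        soft = 1.0 if denom == 0 else 2.0 * (p_c * g_c).sum() / denom
        losses.append(1.0 - soft)
    return float(np.mean(losses))


def _focal_term(pred: np.ndarray, g: np.ndarray, alpha: float, gamma: float) -> np.ndarray:
    """Per-pixel focal cross-entropy α(1-p_t)^γ (-ln p_t)."""
    p = np.clip(pred, _CLIP, 1 - _CLIP)
    p_t = np.where(g == 1, p, 1.0 - p)
    return alpha * (1.0 - p_t) ** gamma * (-np.log(p_t))


def dice_focal_loss(
    pred_probs: np.ndarray,
    true_mask: np.ndarray,
    alpha: float = 0.25,
    gamma: float = 2.0,
) -> float:
    """Combined training objective: soft-dice loss + mean focal term.

    Accepts C x H x W or N x C x H x W probability maps over the two
    foreground channels with a matching binary mask. Non-negative, and → 0
    exactly when predictions match the mask at the clip boundary.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    pred = np.asarray(pred_probs, dtype=np.float64)
    g = np.asarray(true_mask, dtype=np.float64)
    if pred.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs mask {g.shape}")
    dice_term = soft_dice_loss(pred, g)
    focal = float(_focal_term(pred, g, alpha, gamma).mean())
    return dice_term + focal


def dice_focal_gradient(
    pred_probs: np.ndarray,
    true_mask: np.ndarray,
    alpha: float = 0.25,
    gamma: float = 2.0,
) -> np.ndarray:
    """Analytic ∂loss/∂P of :func:`dice_focal_loss`, same shape as ``pred``.

    Used by the reference segmenter's backward pass. The soft-dice part
    differentiates the per-channel ratio; the focal part differentiates
    α(1-p_t)^γ(-ln p_t) through the p_t switch. Pixels clipped out of
    (CLIP, 1-CLIP) get zero focal gradient, matching the clipped forward.
    """
    pred = np.asarray(pred_probs, dtype=np.float64)
    g = np.asarray(true_mask, dtype=np.float64)
    squeeze = pred.ndim == 3
    if squeeze:
        pred, g = pred[None], g[None]
    n_ch = pred.shape[1]

    grad = np.zeros_like(pred)
    # soft-dice term: d/dP_i [1 - 2 T / S] = -2 (G_i S - T) / S^2, / n_ch
    for c in range(n_ch):
        p_c, g_c = pred[:, c], g[:, c]
        s = p_c.sum() + g_c.sum()
        if s > 0:
            t = (p_c * g_c).sum()
            grad[:, c] = -2.0 * (g_c * s - t) / (s * s) / n_ch

    # focal term, averaged over every pixel of every channel
    p = np.clip(pred, _CLIP, 1 - _CLIP)
    inside = (pred > _CLIP) & (pred < 1 - _CLIP)
    one_m_p = 1.0 - p
    # G=1: d/dP α(1-P)^γ(-ln P) = α [ γ(1-P)^(γ-1) ln P - (1-P)^γ / P ]
    g1 = alpha * (gamma * one_m_p ** max(gamma - 1, 0) * np.log(p) - one_m_p**gamma / p)
    # G=0: d/dP α P^γ(-ln(1-P)) = α [ -γ P^(γ-1) ln(1-P) + P^γ / (1-P) ]
    g0 = alpha * (-gamma * p ** max(gamma - 1, 0) * np.log(one_m_p) + p**gamma / one_m_p)
    focal_grad = np.where(g == 1, g1, g0) * inside / pred[0, 0].size / n_ch / pred.shape[0]
    grad += focal_grad
    return grad[0] if squeeze else grad
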