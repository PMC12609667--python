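"""Compound segmentation objective: 0.5 * cross-entropy + 0.5 * weighted Dice.

Nanowire pixels are rare, so the Dice term is class-weighted (inverse
per-batch frequency by default); cross-entropy stays unweighted.  All
functions accept either raw numpy logits or autograd tensors and return an
autograd scalar so the same code path serves evaluation and training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass
class LossConfig:
    ce_weight: float = 0.5
    dice_weight: float = 0.5
    dice_smooth: float = 1e-6
    class_weighting: str = "inverse_frequency"  # or "none"

    def __post_init__(self):
        if abs(self.ce_weight + self.dice_weight - 1.0) > 1e-9:
            raise ValueError("ce_weight + dice_weight must equal 1")
        if self.dice_smooth <= 0:
            raise ValueError("dice_smooth must be positive")
        if self.class_weighting not in ("none", "inverse_frequency"):
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")


def _check_mask(mask: np.ndarray, num_classes: int) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= num_classes:
        raise ValueError(f"mask values must lie in [0, {num_classes - 1}]")
    return mask.astype(np.int64)


def _one_hot(mask: np.ndarray, num_classes: int) -> np.ndarray:
    # mask (N, H, W) -> (N, C, H, W)
    eye = np.eye(num_classes, dtype=np.float32)
    return np.moveaxis(eye[mask], -1, 1)


def _prep(logits, mask):
    logits = nn.as_tensor(logits)
    if logits.ndim == 3:
        logits = nn.reshape(logits, (1,) + logits.shape)
    mask = np.asarray(mask)
    if mask.ndim == 2:
        mask = mask[None]
    nc = logits.shape[1]
    mask = _check_mask(mask, nc)
    if mask.shape != (logits.shape[0],) + logits.shape[2:]:
        raise ValueError(f"mask shape {mask.shape} does not match logits {logits.shape}")
    return logits, mask, nc


def cross_entropy(logits, mask) -> nn.Tensor:
    """Mean over pixels of -log softmax probability of the reference class."""
    logits, mask, nc = _prep(logits, mask)
    logp = nn.log_softmax(logits, axis=1)
    onehot = _one_hot(mask, nc)
    picked = nn.tsum(nn.mul(logp, nn.Tensor(onehot)), axis=1)
    return nn.mul(nn.tmean(picked), -1.0)


def weighted_dice(probs, mask, cfg: LossConfig | None = None) -> nn.Tensor:
    """1 - sum_c w_c * (2 * |P_c ∩ Y_c| + s) / (|P_c| + |Y_c| + s).

    ``probs`` are softmax outputs; weights are normalized to sum to one
    (inverse class frequency of the reference mask, or uniform).
    """
    cfg = cfg or LossConfig()
    probs = nn.as_tensor(probs)
    if probs.ndim == 3:
        probs = nn.reshape(probs, (1,) + probs.shape)
    mask = np.asarray(mask)
    if mask.ndim == 2:
        mask = mask[None]
    nc = probs.shape[1]
    mask = _check_mask(mask, nc)
    onehot = _one_hot(mask, nc)
    counts = onehot.sum(axis=(0, 2, 3))
    if cfg.class_weighting == "inverse_frequency":
        w = 1.0 / np.maximum(counts, 1.0)
    else:
        w = np.ones(nc)
    w = (w / w.sum()).astype(np.float32)
    s = cfg.dice_smooth
    inter = nn.tsum(nn.mul(probs, nn.Tensor(onehot)), axis=(0, 2, 3))
    denom = nn.add(nn.tsum(probs, axis=(0, 2, 3)), counts)
    dice_c = nn.mul(nn.add(nn.mul(inter, 2.0), s), nn.power(nn.add(denom, s), -1.0))
    return nn.add(1.0, nn.mul(nn.tsum(nn.mul(dice_c, nn.Tensor(w))), -1.0))


def combined_loss(logits, mask, cfg: LossConfig | None = None) -> nn.Tensor:
    """ce_weight * CE + dice_weight * weighted Dice (on softmax of the logits)."""
    cfg = cfg or LossConfig()
    ce = cross_entropy(logits, mask)
    logits_t = nn.as_tensor(logits)
    if logits_t.ndim == 3:
        logits_t = nn.reshape(logits_t, (1,) + logits_t.shape)
    probs = nn.softmax(logits_t, axis=1)
    dice = weighted_dice(probs, mask, cfg)
    return nn.add(nn.mul(ce, cfg.ce_weight), nn.mul(dice, cfg.dice_weight))
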