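"""Orthonormal 2-D Haar analysis/synthesis operators.

The segmentation network downsamples by splitting each feature map into the
four Haar subbands (LL approximation plus LH/HL/HH details) on non-overlapping
2x2 blocks, and later recombines them with the exact inverse transform.  This
module holds those operators as pure numpy functions; the trainable layers
wrap them.

Conventions
-----------
* Kernels are the classic sign patterns

      f_LL = [[ 1,  1], [ 1,  1]]      f_LH = [[-1, -1], [ 1,  1]]
      f_HL = [[-1,  1], [-1,  1]]      f_HH = [[ 1, -1], [-1,  1]]

  scaled by ``norm = 1/2`` so the four flattened kernels form an orthonormal
  basis of R^4: the synthesis operator is then the transpose of the analysis
  operator and reconstruction is exact.
* Decomposition uses stride-2 *valid* cross-correlation, i.e. the 2x2 kernels
  tile an even-sized input exactly; odd inputs are edge-replicated to even
  size first (`pad_to_even`).
* Arrays may carry any number of leading axes (``[C, H, W]`` or
  ``[N, C, H, W]``); the transform acts on the trailing two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FilterBank",
    "SubbandSet",
    "haar_filter_bank",
    "pad_to_even",
    "hwt_decompose",
    "dwt_level",
    "iwt_reconstruct",
]

_SUPPORTED_LEVELS = (1, 2)


@dataclass(frozen=True)
class FilterBank:
    """The four 2x2 Haar kernels plus their common normalization scalar."""

    f_ll: np.ndarray
    f_lh: np.ndarray
    f_hl: np.ndarray
    f_hh: np.ndarray
    norm: float

    def kernels(self) -> np.ndarray:
        """Normalized kernels stacked as ``[4, 2, 2]`` in LL, LH, HL, HH order."""
        return self.norm * np.stack([self.f_ll, self.f_lh, self.f_hl, self.f_hh])


@dataclass
class SubbandSet:
    """One decomposition level: approximation ``ll`` and details ``lh, hl, hh``."""

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray
    level: int = 1

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.ll, self.lh, self.hl, self.hh)}
        if len(shapes) != 1:
            raise ValueError(f"subband shapes differ: {sorted(shapes)}")
        if self.level < 1:
            raise ValueError("decomposition level must be positive")

    def stack(self) -> np.ndarray:
        """Subbands concatenated along a new leading axis ``[4, ..., H', W']``."""
        return np.stack([self.ll, self.lh, self.hl, self.hh])

    def concat_channels(self) -> np.ndarray:
        """Channel-wise concatenation ``[..., 4C, H', W']`` (LL block first)."""
        return np.concatenate([self.ll, self.lh, self.hl, self.hh], axis=-3)


def haar_filter_bank() -> FilterBank:
    """Build the orthonormal Haar bank (sign patterns above, ``norm = 1/2``)."""
    f_ll = np.array([[1.0, 1.0], [1.0, 1.0]])
    f_lh = np.array([[-1.0, -1.0], [1.0, 1.0]])
    f_hl = np.array([[-1.0, 1.0], [-1.0, 1.0]])
    f_hh = np.array([[1.0, -1.0], [-1.0, 1.0]])
    return FilterBank(f_ll, f_lh, f_hl, f_hh, norm=0.5)


def pad_to_even(x: np.ndarray) -> np.ndarray:
    """Edge-replicate the trailing two axes to even size (no-op if already even)."""
    ph = x.shape[-2] % 2
    pw = x.shape[-1] % 2
    if not (ph or pw):
        return x
    pad = [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(x, pad, mode="edge")


def hwt_decompose(x: np.ndarray, bank: FilterBank | None = None) -> SubbandSet:
    """Single-level Haar decomposition of ``x`` (trailing dims must be even).

    Each subband is the stride-2 valid cross-correlation of ``x`` with the
    corresponding normalized kernel, so output spatial dims are exactly
    ``(H/2, W/2)``.
    """
    if bank is None:
        bank = haar_filter_bank()
    h, w = x.shape[-2], x.shape[-1]
    if h % 2 or w % 2:
        raise ValueError(
            f"spatial dims must be even, got {(h, w)}; use pad_to_even() first"
        )
    blocks = x.reshape(*x.shape[:-2], h // 2, 2, w // 2, 2)
    blocks = np.moveaxis(blocks, -3, -2)  # [..., H/2, W/2, 2, 2]
    sub = np.einsum("...ij,kij->k...", blocks, bank.kernels())
    return SubbandSet(ll=sub[0], lh=sub[1], hl=sub[2], hh=sub[3], level=1)


def dwt_level(x: np.ndarray, bank: FilterBank | None = None, level: int = 1) -> SubbandSet:
    """Haar decomposition tagged with its cascade ``level``.

    ``level=1`` is identical to :func:`hwt_decompose`; ``level=2`` is meant to
    be called on the level-1 LL branch (the math is the same, only the tag
    differs).  Depths beyond 2 are not part of the extraction block and are
    rejected.
    """
    if level not in _SUPPORTED_LEVELS:
        raise ValueError(f"unsupported decomposition level {level}; expected one of {_SUPPORTED_LEVELS}")
    s = hwt_decompose(x, bank)
    s.level = level
    return s


def iwt_reconstruct(s: SubbandSet, bank: FilterBank | None = None) -> np.ndarray:
    """Exact inverse of :func:`hwt_decompose` under the orthonormal bank."""
    if bank is None:
        bank = haar_filter_bank()
    sub = s.stack()  # [4, ..., H', W']
    blocks = np.einsum("k...,kij->...ij", sub, bank.kernels())  # [..., H', W', 2, 2]
    blocks = np.moveaxis(blocks, -2, -3)  # [..., H', 2, W', 2]
    h2, w2 = s.ll.shape[-2], s.ll.shape[-1]
    return blocks.reshape(*s.ll.shape[:-2], 2 * h2, 2 * w2)
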