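"""Building blocks of the bilateral segmentation network.

* ``DWCM`` -- dual wavelet convolution module: a Haar-wavelet downsampling
  block (subband split + 1x1 fusion) followed by a two-level wavelet feature
  extraction block that re-analyses the fused map, fuses each level with its
  own 1x1 convolution, and synthesises back with the exact inverse transform.
* ``FUM`` -- flexible upsampling module: predicts bounded, input-conditioned
  sampling offsets, remaps them channel-to-space by pixel shuffle, bilinearly
  samples the input at the offset grid, and refines with conv-BN-ReLU.
* ``ARM`` -- attention refinement module (channel attention from GAP).
* ``FFM`` -- feature fusion module (concat + 3x3 conv + residual channel
  recalibration).

All blocks take NCHW `nn.Tensor`s and are differentiable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass
class DwcmConfig:
    in_channels: int
    out_channels: int
    levels: int = 2

    def __post_init__(self):
        if self.levels != 2:
            raise ValueError("the extraction block is defined for exactly two wavelet levels")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")


@dataclass
class FumConfig:
    channels: int
    scale: int
    groups: int = 4
    offset_range: float = 0.5

    def __post_init__(self):
        if self.scale < 1:
            raise ValueError("upsampling scale must be >= 1")
        if self.channels % self.groups:
            raise ValueError(
                f"channels ({self.channels}) must be divisible by groups ({self.groups})"
            )


class WaveletDownsample(nn.Module):
    """Haar subband split + channel fusion: (N, Cin, H, W) -> (N, Cout, H/2, W/2).

    The four subbands are concatenated channel-wise (4*Cin channels at half
    resolution) and fused by 1x1 conv -> BN -> ReLU into ``out_channels``.
    """

    def __init__(self, in_channels: int, out_channels: int, rng=None):
        super().__init__()
        self.fuse = nn.ConvBNReLU(4 * in_channels, out_channels, 1, rng=rng)

    def forward(self, x):
        return self.fuse(nn.haar_dwt(x))


class WaveletExtract(nn.Module):
    """Two-level wavelet feature extraction: (N, C, H', W') -> (N, 4C, H', W').

    Level 1 decomposes the input; level 2 decomposes the level-1 LL branch.
    Each level's subbands pass through their own 1x1 convolutions, the level-2
    result is synthesised back to the level-1 grid and added to the level-1
    LL component, and a final inverse transform returns to the input grid
    before the closing 1x1 channel expansion.  All convolutions here are
    linear (no BN/ReLU), so with identity weights the block is an exact
    analysis/synthesis round trip.
    """

    def __init__(self, channels: int, rng=None):
        super().__init__()
        c4 = 4 * channels
        self.channels = channels
        self.conv_l1 = nn.Conv2d(c4, c4, 1, rng=rng)
        self.conv_l2 = nn.Conv2d(c4, c4, 1, rng=rng)
        self.fuse_l1 = nn.Conv2d(c4, c4, 1, rng=rng)
        self.fuse_l2 = nn.Conv2d(c4, c4, 1, rng=rng)
        self.proj = nn.Conv2d(channels, c4, 1, rng=rng)

    def forward(self, x):
        c = self.channels
        a1 = self.conv_l1(nn.haar_dwt(x))            # level-1 subbands, fused
        ll1 = nn.narrow(a1, 1, 0, c)
        a2 = self.conv_l2(nn.haar_dwt(ll1))          # level-2 subbands of the LL branch
        y1 = self.fuse_l1(a1)
        y2 = self.fuse_l2(a2)
        z2 = nn.haar_iwt(y2)                         # level-2 synthesis to the level-1 grid
        ll = nn.add(nn.narrow(y1, 1, 0, c), z2)
        merged = nn.concat([ll, nn.narrow(y1, 1, c, 3 * c)], axis=1)
        return self.proj(nn.haar_iwt(merged))


class DWCM(nn.Module):
    """Dual wavelet convolution module: one spatial-path downsampling stage.

    downsample (Haar split + fusion to Cout) -> extraction (to 4*Cout) ->
    lightweight 1x1 compression back to Cout.  Halves spatial dims once.
    The wavelet kernels themselves are fixed (non-trainable).
    """

    def __init__(self, in_channels: int, out_channels: int, rng=None):
        super().__init__()
        self.cfg = DwcmConfig(in_channels, out_channels)
        self.down = WaveletDownsample(in_channels, out_channels, rng=rng)
        self.extract = WaveletExtract(out_channels, rng=rng)
        self.compress = nn.ConvBNReLU(4 * out_channels, out_channels, 1, rng=rng)

    def forward(self, x):
        return self.compress(self.extract(self.down(x)))


class FUM(nn.Module):
    """Flexible upsampling module: (N, C, H, W) -> (N, C, H*r, W*r).

    An offset map with 2*g*r^2 channels is produced by two pointwise linear
    maps composed as ``offset_range * sigmoid(a(x)) * b(x)`` (a bounded,
    input-conditioned gate; cap 0.5 by default), pixel-shuffled to the fine
    grid, added (in input-pixel units) to the regular half-pixel sampling
    grid, and used to bilinearly sample the input per channel group.  A
    1x1 conv -> BN -> ReLU tail fuses channels.  The offset branch ``b`` is
    zero-initialized so an untrained module starts at plain bilinear
    upsampling.
    """

    def __init__(self, channels: int, scale: int, groups: int = 4,
                 offset_range: float = 0.5, rng=None, relu_tail: bool = True):
        super().__init__()
        self.cfg = FumConfig(channels, scale, groups, offset_range)
        r = scale
        n_off = 2 * groups * r * r
        self.offset_gate = nn.Conv2d(channels, n_off, 1, rng=rng)
        self.offset_lin = nn.Conv2d(channels, n_off, 1, rng=rng)
        self.offset_lin.weight.data[:] = 0.0
        self.offset_lin.bias.data[:] = 0.0
        self.tail = nn.ConvBNReLU(channels, channels, 1, rng=rng, relu_tail=relu_tail)

    def forward(self, x):
        x = nn.as_tensor(x)
        cfg = self.cfg
        n, c, h, w = x.shape
        r, g = cfg.scale, cfg.groups
        ho, wo = h * r, w * r
        gate = nn.sigmoid(self.offset_gate(x))
        off = nn.mul(nn.mul(gate, cfg.offset_range), self.offset_lin(x))  # (n, 2g r^2, h, w)
        off = nn.pixel_shuffle(off, r)                                    # (n, 2g, ho, wo)
        off = nn.reshape(off, (n, g, 2, ho, wo))
        off = nn.permute(off, (0, 1, 3, 4, 2))                            # (n, g, ho, wo, 2)
        # offsets are in input-pixel units; normalized grid spans 2/W per pixel
        unit = np.array([2.0 / w, 2.0 / h], dtype=np.float32)
        off = nn.mul(off, nn.Tensor(unit))
        base = nn.Tensor(np.broadcast_to(nn.identity_grid(1, ho, wo), (n * g, ho, wo, 2)).copy())
        grid = nn.add(nn.reshape(off, (n * g, ho, wo, 2)), base)
        xg = nn.reshape(x, (n * g, c // g, h, w))
        sampled = nn.grid_sample(xg, grid)
        sampled = nn.reshape(sampled, (n, c, ho, wo))
        return self.tail(sampled)


class ARM(nn.Module):
    """Attention refinement: x * sigmoid(BN(conv1x1(GAP(x)))), broadcast over space."""

    def __init__(self, channels: int, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(channels, channels, 1, rng=rng)
        self.bn = nn.BatchNorm2d(channels)

    def attention(self, x):
        return nn.sigmoid(self.bn(self.conv(nn.global_avg_pool(x))))

    def forward(self, x):
        return nn.mul(nn.as_tensor(x), self.attention(x))


class FFM(nn.Module):
    """Feature fusion of the spatial and context branches at 1/8 scale.

    h = ReLU(BN(conv3x3(concat))); w = sigmoid(BN(conv1x1(GAP(h))));
    out = h + h * w  (so out = h * (1 + w)).
    """

    def __init__(self, spatial_channels: int, context_channels: int,
                 out_channels: int, rng=None):
        super().__init__()
        self.block = nn.ConvBNReLU(spatial_channels + context_channels, out_channels, 3,
                                   padding=1, rng=rng)
        self.att_conv = nn.Conv2d(out_channels, out_channels, 1, rng=rng)
        self.att_bn = nn.BatchNorm2d(out_channels)

    def forward(self, spatial, context):
        spatial, context = nn.as_tensor(spatial), nn.as_tensor(context)
        if spatial.shape[2:] != context.shape[2:]:
            raise ValueError(
                f"spatial {spatial.shape[2:]} and context {context.shape[2:]} dims must match"
            )
        h = self.block(nn.concat([spatial, context], axis=1))
        w = nn.sigmoid(self.att_bn(self.att_conv(nn.global_avg_pool(h))))
        return nn.add(h, nn.mul(h, w))
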