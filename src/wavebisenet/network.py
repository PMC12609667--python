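"""Assembly of the bilateral segmentation network and its ablation variants.

The spatial path preserves detail at 1/8 resolution (three wavelet
downsampling stages, or three stride-2 convolutions in the baseline); the
context path is a ResNet-18-style backbone with channel attention at the
1/16 and 1/32 scales plus a global-average-pooling branch, brought to 1/8 by
a dynamic upsampler (or bilinear in the baseline).  A feature fusion module
merges the two, a 1x1 classifier produces per-class scores at 1/8, and a
final x8 upsampler returns logits at input resolution.

Variants (ablation rows): ``wavebisenet``, ``bisenetv1``,
``bisenetv1+dwcm`` (wavelet spatial path, bilinear upsampling) and
``bisenetv1+fum`` (conv spatial path, dynamic upsampling).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .blocks import ARM, DWCM, FFM, FUM

VARIANTS = ("wavebisenet", "bisenetv1", "bisenetv1+dwcm", "bisenetv1+fum")

CHECKPOINT_VERSION = 1


@dataclass
class NetworkConfig:
    num_classes: int = 2
    input_size: tuple[int, int] = (512, 512)
    spatial_channels: tuple[int, int, int] = (64, 128, 256)
    ffm_channels: int = 256
    context_channels: int = 128
    backbone: str = "resnet18_random"
    variant: str = "wavebisenet"
    width_mult: float = 1.0
    fum_groups: int = 4

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.backbone not in ("resnet18_random", "resnet18_pretrained"):
            raise ValueError(f"unknown backbone {self.backbone!r}")

    def scaled(self, c: int) -> int:
        """Apply width_mult, keeping at least 4 channels (FUM group divisibility)."""
        return max(4, int(round(c * self.width_mult)))


class BasicBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int = 1, rng=None):
        super().__init__()
        self.conv1 = nn.ConvBNReLU(in_ch, out_ch, 3, stride=stride, padding=1, rng=rng)
        self.conv2 = nn.Conv2d(in_ch=out_ch, out_ch=out_ch, kernel=3, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.shortcut = None
        if stride != 1 or in_ch != out_ch:
            self.shortcut = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
                nn.BatchNorm2d(out_ch),
            )

    def forward(self, x):
        y = self.bn2(self.conv2(self.conv1(x)))
        sc = self.shortcut(x) if self.shortcut is not None else nn.as_tensor(x)
        return nn.relu(nn.add(y, sc))


class ResNet18(nn.Module):
    """Four-stage ResNet-18 topology returning 1/4, 1/8, 1/16, 1/32 features."""

    def __init__(self, base: int = 64, in_ch: int = 3, rng=None):
        super().__init__()
        self.stem = nn.ConvBNReLU(in_ch, base, 7, stride=2, padding=3, rng=rng)
        chs = [base, 2 * base, 4 * base, 8 * base]
        self.channels = chs
        self.layer1 = nn.Sequential(BasicBlock(base, chs[0], 1, rng), BasicBlock(chs[0], chs[0], 1, rng))
        self.layer2 = nn.Sequential(BasicBlock(chs[0], chs[1], 2, rng), BasicBlock(chs[1], chs[1], 1, rng))
        self.layer3 = nn.Sequential(BasicBlock(chs[1], chs[2], 2, rng), BasicBlock(chs[2], chs[2], 1, rng))
        self.layer4 = nn.Sequential(BasicBlock(chs[2], chs[3], 2, rng), BasicBlock(chs[3], chs[3], 1, rng))

    def forward(self, x):
        x = self.stem(x)
        x = nn.max_pool2d(x, kernel=3, stride=2, padding=1)
        f4 = self.layer1(x)
        f8 = self.layer2(f4)
        f16 = self.layer3(f8)
        f32 = self.layer4(f16)
        return f4, f8, f16, f32


class BilateralSegNet(nn.Module):
    """The full two-path network; see the module docstring for the layout."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c1, c2, c3 = (cfg.scaled(c) for c in cfg.spatial_channels)
        ctx = cfg.scaled(cfg.context_channels)
        cf = cfg.scaled(cfg.ffm_channels)
        base = cfg.scaled(64)
        wavelet_spatial = cfg.variant in ("wavebisenet", "bisenetv1+dwcm")
        dynamic_up = cfg.variant in ("wavebisenet", "bisenetv1+fum")
        self.dynamic_up = dynamic_up

        if wavelet_spatial:
            self.spatial = nn.Sequential(DWCM(3, c1, rng), DWCM(c1, c2, rng), DWCM(c2, c3, rng))
        else:
            self.spatial = nn.Sequential(
                nn.ConvBNReLU(3, c1, 3, stride=2, padding=1, rng=rng),
                nn.ConvBNReLU(c1, c2, 3, stride=2, padding=1, rng=rng),
                nn.ConvBNReLU(c2, c3, 3, stride=2, padding=1, rng=rng),
            )

        self.backbone = ResNet18(base, rng=rng)
        ch16, ch32 = self.backbone.channels[2], self.backbone.channels[3]
        self.arm16 = ARM(ch16, rng)
        self.arm32 = ARM(ch32, rng)
        self.gap_conv = nn.ConvBNReLU(ch32, ch32, 1, rng=rng)
        self.head16 = nn.ConvBNReLU(ch16, ctx, 1, rng=rng)
        self.head32 = nn.ConvBNReLU(ch32, ctx, 1, rng=rng)
        self.up32 = FUM(ctx, 4, groups=cfg.fum_groups, rng=rng) if dynamic_up else None
        self.ffm = FFM(c3, ctx, cf, rng)
        self.classifier = nn.Conv2d(cf, cfg.num_classes, 1, rng=rng)
        # the final x8 upsampler works on the num_classes-channel map; a class
        # count below the default group count forces single-group offsets, and
        # the tail stays linear because class scores must keep their sign
        self.head_up = (
            FUM(cfg.num_classes, 8, groups=1, rng=rng, relu_tail=False)
            if dynamic_up else None
        )

    def forward(self, x, collect: dict | None = None):
        x = nn.as_tensor(x)
        if x.ndim == 3:
            x = nn.reshape(x, (1,) + x.shape)
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(
                f"input dims {(h, w)} must be divisible by 32; pad to "
                f"({-(-h // 32) * 32}, {-(-w // 32) * 32}) first"
            )
        sp = x
        for i, stage in enumerate(self.spatial.layers, start=1):
            sp = stage(sp)
            if collect is not None:
                collect[f"spatial_{i}"] = sp.shape
        f4, f8, f16, f32 = self.backbone(x)
        if collect is not None:
            collect["context_4"] = f4.shape
            collect["context_8"] = f8.shape
            collect["context_16"] = f16.shape
            collect["context_32"] = f32.shape
        g = self.gap_conv(nn.global_avg_pool(f32))
        c32 = self.head32(nn.add(self.arm32(f32), g))
        c32 = self.up32(c32) if self.up32 is not None else nn.upsample_bilinear(c32, 4)
        c16 = nn.upsample_bilinear(self.head16(self.arm16(f16)), 2)
        context = nn.add(c32, c16)
        fused = self.ffm(sp, context)
        if collect is not None:
            collect["ffm"] = fused.shape
        scores = self.classifier(fused)
        if self.head_up is not None:
            logits = self.head_up(scores)
        else:
            logits = nn.upsample_bilinear(scores, 8)
        return logits


def build_network(cfg: NetworkConfig, seed: int = 0) -> BilateralSegNet:
    """Instantiate a variant with He-initialized weights from ``seed``."""
    if cfg.backbone == "resnet18_pretrained":
        raise NotImplementedError(
            "pretrained backbone weights require an external checkpoint; "
            "load one with load_checkpoint() or use backbone='resnet18_random'"
        )
    return BilateralSegNet(cfg, seed=seed)


def predict_mask(net: BilateralSegNet, image) -> np.ndarray:
    """Argmax class map (ties break to the lowest class index)."""
    net.eval()
    with nn.no_grad():
        logits = net(image).data
    if logits.ndim == 4 and logits.shape[0] == 1:
        logits = logits[0]
    # np.argmax returns the first maximal index, i.e. the lowest class on ties
    return np.argmax(logits, axis=-3).astype(np.uint8)


def save_checkpoint(path, net: BilateralSegNet, extra: dict | None = None) -> None:
    cfg = asdict(net.cfg)
    meta = {"version": CHECKPOINT_VERSION, "config": cfg, "extra": extra or {}}
    state = net.state_dict()
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        buf = io.BytesIO()
        np.savez(buf, **state)
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path) -> tuple[BilateralSegNet, dict]:
    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(zf.read("meta.json"))
        with zf.open("weights.npz") as f:
            state = dict(np.load(io.BytesIO(f.read())))
    cfg_d = meta["config"]
    for key in ("input_size", "spatial_channels"):
        cfg_d[key] = tuple(cfg_d[key])
    net = BilateralSegNet(NetworkConfig(**cfg_d), seed=0)
    net.load_state_dict(state)
    return net, meta
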