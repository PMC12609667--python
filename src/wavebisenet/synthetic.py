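"""Synthetic nanowire micrographs, threshold/morphology annotation, dataset protocol.

The generator emulates bright-field TEM images of peptide nanowires: dark,
slender, curvilinear fibers on a brighter, unevenly illuminated, blurred and
noisy background.  Two regimes are modelled -- ``dispersed`` (few fibers,
slight overlap) and ``network`` (dense entangled webs with many crossings).
Fibers are integrated random-heading walks (heading increments drawn from a
normal with std ``curvature``) rendered at a given stroke width into a hard
binary mask; image-side softness comes only from the Gaussian blur.

The annotation pipeline mirrors a classic threshold + morphology recipe:
3x3 median filter, HSV conversion (grayscale replicated to RGB, so S = 0 and
the V threshold governs), dual thresholds S < 40 and V < 90, one opening, two
closings, and a one-pixel dilation, all with a 3x3 structuring element.

The dataset protocol splits at the source-image level 7:2:1 *before* patch
cropping (so patches never leak across splits), crops a non-overlapping grid
and discards remainder margins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.color import rgb2hsv

STRUCT_3x3 = np.ones((3, 3), dtype=bool)


@dataclass
class SyntheticConfig:
    image_size: tuple[int, int] = (512, 512)
    n_wires: tuple[int, int] = (3, 8)          # inclusive range; regime-dependent default
    wire_width_px: tuple[float, float] = (8.0, 14.0)
    curvature: float = 0.15                    # std of per-step heading increments (radians)
    regime: str = "dispersed"                  # or "network"
    background_level: float = 200.0
    wire_level: float = 60.0
    blur_sigma: float = 1.0
    noise_sd: float = 5.0
    illumination_gradient: float = 15.0        # peak-to-peak ramp amplitude (gray levels)
    seed: int = 0

    def __post_init__(self):
        if self.regime not in ("dispersed", "network"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.wire_level >= self.background_level:
            raise ValueError("fibers must be darker than the background (TEM bright field)")
        if self.n_wires[0] > self.n_wires[1] or self.wire_width_px[0] > self.wire_width_px[1]:
            raise ValueError("ranges must be nonempty (lo <= hi)")
        if self.wire_width_px[1] > min(self.image_size):
            raise ValueError("wire width exceeds the image size")

    @classmethod
    def for_regime(cls, regime: str, **kw) -> "SyntheticConfig":
        """Regime presets: dense entangled webs carry ~4x more fibers."""
        if regime == "network":
            kw.setdefault("n_wires", (12, 25))
            kw.setdefault("curvature", 0.25)
        return cls(regime=regime, **kw)


def micro_config(seed: int, regime: str = "dispersed") -> SyntheticConfig:
    """Desk-scale preset: 64x64 patches with 1-3 (dispersed) or 2-4 (network)
    fibers, the same contrast/noise settings as full scale.

    Stroke width 8-12 px: the network scores pixels on a 1/8-scale grid whose
    cell is 8 px regardless of image size, so fibers much thinner than one
    cell are unrepresentable by any weights; widths at or above one cell keep
    the desk-scale task in the same feature-size-to-prediction-scale regime
    as full-resolution micrographs.
    """
    n_wires = (1, 3) if regime == "dispersed" else (2, 4)
    return SyntheticConfig(image_size=(64, 64), n_wires=n_wires,
                           wire_width_px=(8.0, 12.0), regime=regime, seed=seed)


def generate_set(n: int, seed: int = 0,
                 config_fn=micro_config) -> list["SegmentationSample"]:
    """n reproducible samples; seeds are ``seed + i`` through ``config_fn``."""
    return [generate_sample(config_fn(seed + i)) for i in range(n)]


@dataclass
class SegmentationSample:
    image: np.ndarray  # uint8 [H, W]
    mask: np.ndarray   # uint8 {0, 1} [H, W]
    meta: dict = field(default_factory=dict)


@dataclass
class AnnotationParams:
    median_kernel: int = 3
    s_max: int = 40
    v_max: int = 90
    opening_iters: int = 1
    closing_iters: int = 2
    dilation_px: int = 1
    structuring_element: np.ndarray = field(default_factory=lambda: STRUCT_3x3.copy())


def _render_wire(mask: np.ndarray, rng: np.random.Generator, width: float,
                 curvature: float) -> None:
    """Rasterize one random-heading walk of stroke ``width`` into ``mask`` (in place)."""
    h, w = mask.shape
    n_steps = int(rng.uniform(0.6, 1.4) * max(h, w))
    pos = rng.uniform([0.1 * h, 0.1 * w], [0.9 * h, 0.9 * w])
    heading = rng.uniform(0.0, 2.0 * np.pi)
    pts = np.empty((n_steps, 2))
    for i in range(n_steps):
        pts[i] = pos
        heading += rng.normal(0.0, curvature)
        pos = pos + [np.sin(heading), np.cos(heading)]
    # keep the centerline mostly inside the frame
    pts = pts[(pts[:, 0] >= -width) & (pts[:, 0] < h + width)
              & (pts[:, 1] >= -width) & (pts[:, 1] < w + width)]
    if pts.size == 0:
        return
    centers = np.round(pts).astype(int)
    centers = centers[(centers[:, 0] >= 0) & (centers[:, 0] < h)
                      & (centers[:, 1] >= 0) & (centers[:, 1] < w)]
    line = np.zeros_like(mask)
    line[centers[:, 0], centers[:, 1]] = True
    # thicken the 1-px centerline to the target stroke width via EDT
    r = max(width / 2.0 - 0.5, 0.0)
    if r > 0:
        dist = ndimage.distance_transform_edt(~line)
        mask |= dist <= r
    else:
        mask |= line


def generate_sample(cfg: SyntheticConfig) -> SegmentationSample:
    """Render one image/mask pair; bitwise-reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    mask = np.zeros((h, w), dtype=bool)
    n_wires = int(rng.integers(cfg.n_wires[0], cfg.n_wires[1] + 1))
    for _ in range(n_wires):
        width = rng.uniform(*cfg.wire_width_px)
        _render_wire(mask, rng, width, cfg.curvature)
    yy, xx = np.mgrid[0:h, 0:w]
    direction = rng.uniform(0.0, 2.0 * np.pi)
    ramp = (np.cos(direction) * xx / max(w - 1, 1) + np.sin(direction) * yy / max(h - 1, 1))
    ramp = (ramp - ramp.min()) / max(np.ptp(ramp), 1e-12) - 0.5
    img = np.full((h, w), cfg.background_level, dtype=np.float64)
    img += cfg.illumination_gradient * ramp
    img[mask] = cfg.wire_level + cfg.illumination_gradient * ramp[mask]
    if cfg.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, cfg.blur_sigma)
    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    meta = {"seed": cfg.seed, "regime": cfg.regime, "n_wires": n_wires}
    return SegmentationSample(image=img, mask=mask.astype(np.uint8), meta=meta)


# ---------------------------------------------------------------------------
# annotation pipeline
# ---------------------------------------------------------------------------

def binary_erosion(mask: np.ndarray, structure: np.ndarray = STRUCT_3x3,
                   iterations: int = 1) -> np.ndarray:
    """Erosion that treats the outside of the frame as foreground."""
    return ndimage.binary_erosion(mask, structure=structure, iterations=iterations,
                                  border_value=1)


def binary_dilation(mask: np.ndarray, structure: np.ndarray = STRUCT_3x3,
                    iterations: int = 1) -> np.ndarray:
    """Dilation that treats the outside of the frame as background."""
    return ndimage.binary_dilation(mask, structure=structure, iterations=iterations,
                                   border_value=0)


def binary_opening(mask, structure=STRUCT_3x3, iterations: int = 1) -> np.ndarray:
    out = np.asarray(mask, dtype=bool)
    for _ in range(iterations):
        out = binary_dilation(binary_erosion(out, structure), structure)
    return out


def binary_closing(mask, structure=STRUCT_3x3, iterations: int = 1) -> np.ndarray:
    out = np.asarray(mask, dtype=bool)
    for _ in range(iterations):
        out = binary_erosion(binary_dilation(out, structure), structure)
    return out


def annotate_mask(image: np.ndarray, params: AnnotationParams | None = None) -> np.ndarray:
    """Threshold + morphology annotation of an 8-bit grayscale micrograph.

    Median filter -> HSV (S is identically 0 for replicated grayscale, so the
    V < v_max threshold governs) -> (S < s_max) & (V < v_max) -> opening ->
    closing x2 -> 1 px dilation.  Returns a {0,1} uint8 mask.
    """
    params = params or AnnotationParams()
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError("annotate_mask expects an 8-bit image")
    filtered = ndimage.median_filter(image, size=params.median_kernel)
    rgb = np.stack([filtered] * 3, axis=-1).astype(np.float64) / 255.0
    hsv = rgb2hsv(rgb)
    s = hsv[..., 1] * 255.0
    v = hsv[..., 2] * 255.0
    mask = (s < params.s_max) & (v < params.v_max)
    st = params.structuring_element
    mask = binary_opening(mask, st, params.opening_iters)
    mask = binary_closing(mask, st, params.closing_iters)
    mask = binary_dilation(mask, st, params.dilation_px)
    return mask.astype(np.uint8)


# ---------------------------------------------------------------------------
# dataset protocol: split at source level, crop a non-overlapping grid
# ---------------------------------------------------------------------------

@dataclass
class PatchRecord:
    source_id: int
    split: str
    row: int
    col: int
    seed: int | None = None
    regime: str | None = None


@dataclass
class Dataset:
    samples: list[SegmentationSample]
    records: list[PatchRecord]


def split_and_crop(samples: list[SegmentationSample], ratio: tuple[int, int, int] = (7, 2, 1),
                   patch: int = 512, seed: int = 0) -> tuple[Dataset, Dataset, Dataset]:
    """7:2:1 split at the source-image level, then non-overlapping patch grids."""
    if any(r < 0 for r in ratio) or sum(ratio) <= 0:
        raise ValueError(f"invalid split ratio {ratio}")
    if samples and patch > min(min(s.image.shape) for s in samples):
        raise ValueError("patch size exceeds the smallest image dimension")
    n = len(samples)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    denom = sum(ratio)
    n_train = round(n * ratio[0] / denom)
    n_val = round(n * ratio[1] / denom)
    assignment = {}
    for k, src in enumerate(order):
        if k < n_train:
            assignment[src] = "train"
        elif k < n_train + n_val:
            assignment[src] = "val"
        else:
            assignment[src] = "test"
    out = {"train": Dataset([], []), "val": Dataset([], []), "test": Dataset([], [])}
    for src, sample in enumerate(samples):
        split = assignment[src]
        h, w = sample.image.shape
        for i in range(h // patch):
            for j in range(w // patch):
                sl = (slice(i * patch, (i + 1) * patch), slice(j * patch, (j + 1) * patch))
                out[split].samples.append(
                    SegmentationSample(sample.image[sl].copy(), sample.mask[sl].copy(),
                                       dict(sample.meta))
                )
                out[split].records.append(
                    PatchRecord(source_id=src, split=split, row=i, col=j,
                                seed=sample.meta.get("seed"), regime=sample.meta.get("regime"))
                )
    return out["train"], out["val"], out["test"]


def write_dataset(ds: Dataset, directory) -> Path:
    """Write paired PNGs (mask stored as {0, 255}) plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, (sample, rec) in enumerate(zip(ds.samples, ds.records)):
        img_name, mask_name = f"{k:05d}_image.png", f"{k:05d}_mask.png"
        Image.fromarray(sample.image).save(directory / img_name)
        Image.fromarray((sample.mask * 255).astype(np.uint8)).save(directory / mask_name)
        entries.append({"image": img_name, "mask": mask_name, **asdict(rec)})
    manifest = directory / "manifest.json"
    manifest.write_text(json.dumps({"n_samples": len(entries), "entries": entries}, indent=1))
    return manifest


def read_dataset(directory) -> Dataset:
    """Round-trip read; raises naming the offending file on any missing pair."""
    directory = Path(directory)
    manifest = directory / "manifest.json"
    if not manifest.exists():
        raise FileNotFoundError(f"missing manifest: {manifest}")
    spec = json.loads(manifest.read_text())
    samples, records = [], []
    for e in spec["entries"]:
        img_path, mask_path = directory / e["image"], directory / e["mask"]
        for p in (img_path, mask_path):
            if not p.exists():
                raise FileNotFoundError(f"dataset integrity error: missing file {p}")
        try:
            image = np.asarray(Image.open(img_path))
            mask255 = np.asarray(Image.open(mask_path))
        except Exception as exc:
            raise OSError(f"dataset integrity error: unreadable file in pair "
                          f"({img_path}, {mask_path}): {exc}") from exc
        if set(np.unique(mask255)) - {0, 255}:
            raise ValueError(f"dataset integrity error: non-binary mask {mask_path}")
        samples.append(SegmentationSample(image, (mask255 > 0).astype(np.uint8),
                                          {"seed": e.get("seed"), "regime": e.get("regime")}))
        records.append(PatchRecord(source_id=e["source_id"], split=e["split"],
                                   row=e["row"], col=e["col"], seed=e.get("seed"),
                                   regime=e.get("regime")))
    return Dataset(samples, records)
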