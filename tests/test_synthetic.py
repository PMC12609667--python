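"""Synthetic fiber generator, annotation pipeline, dataset split/crop protocol."""

import json

import numpy as np
import pytest
from scipy import ndimage

from wavebisenet import (AnnotationParams, SyntheticConfig, annotate_mask,
                         generate_sample, read_dataset, split_and_crop,
                         write_dataset)
from wavebisenet.synthetic import (binary_closing, binary_dilation, binary_opening,
                                   micro_config)


# -- naive nested-loop morphology oracle (outside-of-frame: erosion sees
#    foreground, dilation sees background) ---------------------------------

def naive_erode(m: np.ndarray) -> np.ndarray:
    h, w = m.shape
    out = np.zeros_like(m, dtype=bool)
    for i in range(h):
        for j in range(w):
            v = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    v &= bool(m[ii, jj]) if 0 <= ii < h and 0 <= jj < w else True
            out[i, j] = v
    return out


def naive_dilate(m: np.ndarray) -> np.ndarray:
    h, w = m.shape
    out = np.zeros_like(m, dtype=bool)
    for i in range(h):
        for j in range(w):
            v = False
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    v |= bool(m[ii, jj]) if 0 <= ii < h and 0 <= jj < w else False
            out[i, j] = v
    return out


def naive_median3(img: np.ndarray) -> np.ndarray:
    padded = np.pad(img, 1, mode="symmetric")
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.median(padded[i : i + 3, j : j + 3])
    return out


def hand_stepped_annotation(img: np.ndarray, v_max: int = 90) -> np.ndarray:
    """The full pipeline re-derived step by step with the naive primitives."""
    med = naive_median3(img)
    # replicated-gray HSV: S = 0 (< 40 always), V = gray level
    m = med < v_max
    m = naive_dilate(naive_erode(m))                    # opening
    for _ in range(2):                                  # two closings
        m = naive_erode(naive_dilate(m))
    return naive_dilate(m)                              # 1 px dilation


class TestGenerator:
    def test_same_seed_is_bitwise_identical(self):
        cfg = SyntheticConfig(image_size=(64, 64), seed=11)
        a, b = generate_sample(cfg), generate_sample(cfg)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)
        assert a.meta == b.meta

    def test_empty_scene(self):
        cfg = SyntheticConfig(image_size=(32, 32), n_wires=(0, 0), noise_sd=0.0,
                              illumination_gradient=0.0, blur_sigma=0.0)
        s = generate_sample(cfg)
        assert s.mask.sum() == 0
        assert np.all(s.image == 200)

    def test_mask_values_binary_and_shape_matches(self):
        s = generate_sample(SyntheticConfig(image_size=(48, 64), seed=3))
        assert set(np.unique(s.mask)) <= {0, 1}
        assert s.image.shape == s.mask.shape == (48, 64)
        assert s.image.dtype == np.uint8

    def test_foreground_fraction_within_analytic_band(self):
        # n_wires * width * mean_length / (H * W), +/- 50 %, averaged over seeds
        fracs = []
        for seed in range(20):
            cfg = SyntheticConfig(image_size=(256, 256), n_wires=(3, 3),
                                  wire_width_px=(5.0, 5.0), seed=seed)
            fracs.append(generate_sample(cfg).mask.mean())
        expect = 3 * 5.0 * 256 / (256 * 256)
        assert 0.5 * expect < np.mean(fracs) < 1.5 * expect

    def test_network_regime_is_denser(self):
        disp = [generate_sample(micro_config(s, "dispersed")).mask.mean() for s in range(8)]
        net = [generate_sample(micro_config(s, "network")).mask.mean() for s in range(8)]
        assert np.mean(net) > np.mean(disp)
        assert all(f < 0.5 for f in net)  # foreground stays the minority class

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError, match="width"):
            SyntheticConfig(image_size=(16, 16), wire_width_px=(20.0, 30.0))

    def test_wires_darker_than_background_enforced(self):
        with pytest.raises(ValueError, match="darker"):
            SyntheticConfig(background_level=60.0, wire_level=200.0)


class TestAnnotation:
    def test_uniformly_bright_image_gives_empty_mask(self):
        img = np.full((16, 16), 200, dtype=np.uint8)
        assert annotate_mask(img).sum() == 0

    def test_uniformly_dark_image_stays_all_foreground(self):
        img = np.full((16, 16), 50, dtype=np.uint8)
        assert annotate_mask(img).all()

    def test_stripe_fixture_matches_hand_stepped_oracle_exactly(self):
        # 3 px dark stripe (V = 60) + one isolated dark pixel on a bright field
        img = np.full((16, 16), 200, dtype=np.uint8)
        img[7:10, :] = 60
        img[2, 2] = 60
        out = annotate_mask(img)
        oracle = hand_stepped_annotation(img)
        assert np.array_equal(out.astype(bool), oracle)
        assert not out[2, 2]                    # isolated pixel removed
        assert out[6:11, :].all()               # stripe survives, widened by 1 px
        assert not out[:5, :].any()

    def test_dual_thresholds_are_both_applied(self):
        # V = 100 exceeds v_max even though S = 0 < 40: no foreground
        img = np.full((8, 8), 100, dtype=np.uint8)
        assert annotate_mask(img).sum() == 0

    def test_recovers_generator_mask_at_low_noise(self):
        # pipeline and generator are mutually consistent: IoU >= 0.7
        ious = []
        for seed in range(20):
            cfg = SyntheticConfig(image_size=(96, 96), n_wires=(2, 3),
                                  wire_width_px=(8.0, 12.0), noise_sd=5.0,
                                  blur_sigma=1.0, seed=seed)
            s = generate_sample(cfg)
            est = annotate_mask(s.image).astype(bool)
            ref = s.mask.astype(bool)
            union = (est | ref).sum()
            ious.append((est & ref).sum() / union if union else 1.0)
        assert np.mean(ious) >= 0.7

    def test_rejects_non_uint8_input(self):
        with pytest.raises(ValueError, match="8-bit"):
            annotate_mask(np.zeros((8, 8), dtype=float))


class TestMorphologyOracle:
    @pytest.mark.parametrize("op, ref", [
        (binary_opening, lambda m: naive_dilate(naive_erode(m))),
        (binary_closing, lambda m: naive_erode(naive_dilate(m))),
        (binary_dilation, naive_dilate),
    ])
    def test_matches_naive_loops_on_random_grids(self, op, ref):
        rng = np.random.default_rng(5)
        for _ in range(100):
            m = rng.random((8, 8)) < 0.4
            assert np.array_equal(op(m).astype(bool), ref(m))


class TestSplitAndCrop:
    def _samples(self, n, size=64, seed=0):
        return [generate_sample(SyntheticConfig(image_size=(size, size),
                                                n_wires=(1, 2), seed=seed + i))
                for i in range(n)]

    def test_exact_split_counts(self):
        tr, va, te = split_and_crop(self._samples(10), patch=64, seed=0)
        assert (len(tr.samples), len(va.samples), len(te.samples)) == (7, 2, 1)

    def test_grid_cropping_counts(self):
        s = self._samples(1, size=128)
        tr, va, te = split_and_crop(s, ratio=(1, 0, 0), patch=64, seed=0)
        assert len(tr.samples) == 4  # 2x2 non-overlapping grid

    def test_no_leakage_across_splits(self):
        tr, va, te = split_and_crop(self._samples(20, size=128), patch=64, seed=3)
        by_split = {}
        for name, ds in (("train", tr), ("val", va), ("test", te)):
            for rec in ds.records:
                by_split.setdefault(rec.source_id, set()).add(name)
        assert all(len(splits) == 1 for splits in by_split.values())

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError, match="patch"):
            split_and_crop(self._samples(2, size=32), patch=64)


class TestDatasetIO:
    def test_round_trip_is_bitwise_equal(self, tmp_path):
        tr, _, _ = split_and_crop(self._gen(6), patch=32, seed=0)
        write_dataset(tr, tmp_path / "train")
        back = read_dataset(tmp_path / "train")
        assert len(back.samples) == len(tr.samples)
        for a, b in zip(tr.samples, back.samples):
            assert np.array_equal(a.image, b.image)
            assert np.array_equal(a.mask, b.mask)

    def test_manifest_counts_files(self, tmp_path):
        tr, _, _ = split_and_crop(self._gen(6), patch=32, seed=0)
        manifest = write_dataset(tr, tmp_path / "d")
        spec = json.loads(manifest.read_text())
        pngs = list((tmp_path / "d").glob("*.png"))
        assert spec["n_samples"] * 2 == len(pngs)

    def test_corrupt_mask_file_is_named_in_the_error(self, tmp_path):
        tr, _, _ = split_and_crop(self._gen(6), patch=32, seed=0)
        write_dataset(tr, tmp_path / "d")
        victim = sorted((tmp_path / "d").glob("*_mask.png"))[0]
        victim.unlink()
        with pytest.raises(FileNotFoundError, match=victim.name):
            read_dataset(tmp_path / "d")

    def _gen(self, n):
        return [generate_sample(SyntheticConfig(image_size=(32, 32), n_wires=(1, 2),
                                                wire_width_px=(4.0, 6.0), seed=i))
                for i in range(n)]
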