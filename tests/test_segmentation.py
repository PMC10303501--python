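import numpy as np
import pytest

from phenofuse.errors import ConfigError, FormatError, SizeError
from phenofuse.segmentation import (
    ObjectROI, ScanImage, SegmentationParams, binarize, extract_objects,
    normalize_to_canvas, segment_scan, to_grayscale,
)


def _disk_mask(h, w, cy, cx, r):
    yy, xx = np.mgrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


class TestGrayscale:
    def test_black_and_white_extremes(self):
        black = np.zeros((4, 5, 3), np.uint8)
        white = np.full((4, 5, 3), 255, np.uint8)
        assert np.all(to_grayscale(black) == 0)
        assert np.allclose(to_grayscale(white), 255)

    def test_matches_hand_computed_luminance(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(6, 7, 3)).astype(np.uint8)
        gray = to_grayscale(img)
        # independent per-pixel recomputation of the weighted sum
        expect = np.empty((6, 7))
        for i in range(6):
            for j in range(7):
                r, g, b = img[i, j].astype(float)
                expect[i, j] = 0.299 * r + 0.587 * g + 0.114 * b
        assert np.allclose(gray, expect, atol=1e-9)

    def test_rejects_non_rgb(self):
        with pytest.raises(FormatError):
            to_grayscale(np.zeros((4, 5), np.uint8))


class TestBinarize:
    def test_fixed_threshold_all_foreground(self):
        gray = np.full((5, 5), 100.0)
        assert binarize(gray, "fixed", threshold=50).all()

    def test_fixed_requires_threshold(self):
        with pytest.raises(ConfigError):
            binarize(np.zeros((3, 3)), "fixed")

    def test_otsu_separates_two_levels_like_exhaustive_search(self):
        rng = np.random.default_rng(1)
        gray = rng.choice([40.0, 200.0], size=(20, 20))
        # oracle: exhaustive threshold search maximizing between-class variance
        vals = np.unique(gray)
        best_t, best_v = None, -1.0
        for t in np.arange(vals.min(), vals.max(), 1.0):
            lo, hi = gray[gray <= t], gray[gray > t]
            if lo.size == 0 or hi.size == 0:
                continue
            w0, w1 = lo.size / gray.size, hi.size / gray.size
            v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if v > best_v:
                best_v, best_t = v, t
        assert np.array_equal(binarize(gray, "otsu"), gray > best_t)

    def test_constant_image_is_all_background(self):
        assert not binarize(np.full((4, 4), 7.0), "otsu").any()

    def test_foreground_count_matches_generator(self, seed_scan):
        scan, truth = seed_scan
        mask = binarize(to_grayscale(scan), "otsu")
        painted = sum(int(m.sum()) for m in truth.masks)
        assert abs(int(mask.sum()) - painted) <= 0.02 * painted


class TestExtractObjects:
    def test_empty_mask(self):
        assert extract_objects(np.zeros((10, 10), bool)) == []

    def test_disks_recovered_with_exact_bboxes(self):
        mask = np.zeros((200, 300), bool)
        centers = [(40, 50), (40, 150), (40, 250), (120, 50), (120, 150), (120, 250)]
        for cy, cx in centers:
            mask |= _disk_mask(200, 300, cy, cx, 15)
        rois = extract_objects(mask, min_area_px=10)
        assert len(rois) == 6
        for roi, (cy, cx) in zip(rois, centers):
            r0, c0, r1, c1 = roi.bbox
            assert abs(r0 - (cy - 15)) <= 1 and abs(r1 - (cy + 16)) <= 1
            assert abs(c0 - (cx - 15)) <= 1 and abs(c1 - (cx + 16)) <= 1

    def test_min_area_drops_speck(self):
        mask = np.zeros((60, 60), bool)
        mask |= _disk_mask(60, 60, 15, 15, 8)
        mask |= _disk_mask(60, 60, 45, 45, 8)
        mask[2, 30:33] = True  # 3-pixel speck
        assert len(extract_objects(mask, min_area_px=10)) == 2

    def test_border_touching_dropped_when_flagged(self):
        mask = np.zeros((50, 50), bool)
        mask |= _disk_mask(50, 50, 0, 25, 8)      # touches top border
        mask |= _disk_mask(50, 50, 30, 25, 8)
        assert len(extract_objects(mask, min_area_px=10)) == 2
        kept = extract_objects(mask, min_area_px=10, drop_border_touching=True)
        assert len(kept) == 1 and kept[0].bbox[0] > 0

    def test_row_major_ordering(self):
        mask = np.zeros((100, 100), bool)
        mask |= _disk_mask(100, 100, 70, 20, 8)
        mask |= _disk_mask(100, 100, 20, 70, 8)
        mask |= _disk_mask(100, 100, 20, 20, 8)
        rois = extract_objects(mask, min_area_px=10)
        tops = [(r.bbox[0], r.bbox[1]) for r in rois]
        assert tops == sorted(tops)

    def test_connectivity_4_vs_8(self):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:5] = True
        mask[5:8, 5:8] = True  # diagonal touch at (4,4)/(5,5)
        assert len(extract_objects(mask, min_area_px=1, connectivity=8)) == 1
        assert len(extract_objects(mask, min_area_px=1, connectivity=4)) == 2


class TestNormalizeToCanvas:
    def _roi_image(self, h, w):
        rng = np.random.default_rng(3)
        px = np.zeros((h + 20, w + 20, 3), np.uint8)
        mask = np.zeros((h, w), bool)
        mask[:] = True
        px[10:10 + h, 10:10 + w] = rng.integers(60, 255, size=(h, w, 3))
        roi = ObjectROI(bbox=(10, 10, 10 + h, 10 + w), area_px=h * w, mask_crop=mask)
        return ScanImage(px, "seed", "c", "s"), roi

    def test_black_pixel_budget(self):
        scan, roi = self._roi_image(50, 80)
        out = normalize_to_canvas(scan, roi, canvas_size=300)
        assert out.pixels.shape == (300, 300, 3)
        n_black = int((out.pixels == 0).all(axis=2).sum())
        assert n_black == 300 * 300 - roi.area_px

    def test_exact_canvas_object_is_pasted_unscaled(self):
        scan, roi = self._roi_image(300, 300)
        out = normalize_to_canvas(scan, roi, canvas_size=300)
        assert out.mask.all()
        assert np.array_equal(out.pixels, scan.pixels[10:310, 10:310])

    def test_overflow_error(self):
        scan, roi = self._roi_image(400, 60)
        with pytest.raises(SizeError):
            normalize_to_canvas(scan, roi, canvas_size=300, overflow="error")

    def test_overflow_rescale_preserves_aspect(self):
        scan, roi = self._roi_image(400, 100)
        out = normalize_to_canvas(scan, roi, canvas_size=300, overflow="rescale")
        assert out.pixels.shape == (300, 300, 3)
        rs, cs = np.nonzero(out.mask)
        h = rs.max() - rs.min() + 1
        w = cs.max() - cs.min() + 1
        assert abs((h / w) / (400 / 100) - 1) < 0.01

    def test_background_outside_mask_is_pure_black(self, seed_scan):
        scan, _ = seed_scan
        for obj in segment_scan(scan):
            assert (obj.pixels[~obj.mask] == 0).all()


class TestSegmentScan:
    def test_recovers_generator_object_count(self, seed_scan, pod_scan):
        for scan, truth in (seed_scan, pod_scan):
            assert len(segment_scan(scan)) == truth.count

    def test_empty_scan_yields_nothing(self):
        scan = ScanImage(np.zeros((100, 120, 3), np.uint8), "seed", "c", "e")
        assert segment_scan(scan) == []

    def test_idempotent_on_normalized_object(self, seed_scan):
        scan, _ = seed_scan
        obj = segment_scan(scan)[0]
        rescan = ScanImage(obj.pixels, "seed", "c", "re")
        again = segment_scan(rescan)
        assert len(again) == 1

    def test_deterministic_byte_identical(self, seed_scan):
        scan, _ = seed_scan
        a = segment_scan(scan, SegmentationParams())
        b = segment_scan(scan, SegmentationParams())
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert np.array_equal(x.pixels, y.pixels)
            assert np.array_equal(x.mask, y.mask)

    def test_area_conserved_without_overflow(self, seed_scan):
        scan, truth = seed_scan
        mask = binarize(to_grayscale(scan), "otsu")
        rois = extract_objects(mask, min_area_px=64)
        for i, roi in enumerate(rois):
            out = normalize_to_canvas(scan, roi, canvas_size=300, overflow="error",
                                      object_index=i)
            assert int(out.mask.sum()) == roi.area_px
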