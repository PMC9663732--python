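import numpy as np
import pytest

from bmdetect.core import Box2D, Volume3D, iou
from bmdetect.detect import (
    AnchorSet,
    BlobDetector,
    BlobDetectorCV,
    DetectorConfig,
    NotNormalizedError,
    augment,
    calibrate_detector,
    detect_slices,
    estimate_anchors,
)
from bmdetect.link import link_boxes
from bmdetect.phantom import generate_scan
from bmdetect.preprocess import BrainMask, extract_brain, normalize_slices
from tests.conftest import small_config


def volume_from_slices(slices):
    data = np.asarray(slices, dtype=np.float32)
    v = Volume3D(data, (1.0, 1.0), 3.0)
    return v, BrainMask(np.ones_like(data, dtype=bool))


class TestDetectSlices:
    def test_bright_disk_yields_one_tight_detection(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disk = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 8**2).astype(np.float32)
        v, m = volume_from_slices([disk])
        boxes = detect_slices(v, m)
        assert len(boxes) == 1
        b = boxes[0]
        # analytic tight box of a radius-8 disk centred at (32, 32)
        for got, want in [(b.x, 24), (b.y, 24), (b.w, 16), (b.h, 16)]:
            assert abs(got - want) <= 1
        assert 0.0 <= b.score <= 1.0

    def test_all_zero_slice_has_no_detections(self):
        v, m = volume_from_slices([np.zeros((32, 32))])
        assert detect_slices(v, m) == []

    def test_thin_line_rejected_by_circularity(self):
        img = np.zeros((64, 80), dtype=np.float32)
        img[30:32, 10:70] = 1.0  # 2 px x 60 px: circularity ~0.1
        v, m = volume_from_slices([img])
        assert detect_slices(v, m) == []
        # the same component passes when the circularity gate is disabled
        assert len(detect_slices(v, m, DetectorConfig(min_circularity=0.0))) == 1

    def test_unnormalized_input_rejected(self):
        v, m = volume_from_slices([np.full((8, 8), 7.0)])
        with pytest.raises(NotNormalizedError):
            detect_slices(v, m)

    def test_output_invariant_to_scan_relabel_and_zero_padding(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disk = ((yy - 20) ** 2 + (xx - 20) ** 2 <= 5**2).astype(np.float32)
        v, m = volume_from_slices([disk, disk])
        base = detect_slices(v, m)
        renamed = Volume3D(v.data, v.pixel_size_mm, v.slice_thickness_mm, scan_id="other")
        assert [
            (b.slice_index, b.x, b.y, b.w, b.h) for b in detect_slices(renamed, m)
        ] == [(b.slice_index, b.x, b.y, b.w, b.h) for b in base]
        padded = Volume3D(
            np.concatenate([v.data, np.zeros_like(v.data[:1])]),
            v.pixel_size_mm, v.slice_thickness_mm,
        )
        m2 = BrainMask(np.concatenate([m.mask, np.ones_like(m.mask[:1])]))
        assert [(b.slice_index, b.x, b.y) for b in detect_slices(padded, m2)] == [
            (b.slice_index, b.x, b.y) for b in base
        ]


class TestAugment:
    def test_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        boxes = [Box2D(0, 1, 0, 2, 2)]
        out, mapped = augment(img, boxes, rot=0, flip_lr=False)
        np.testing.assert_array_equal(out, img)
        assert mapped == boxes

    def test_rot180_coordinate_map(self):
        img = np.zeros((100, 100))
        out, mapped = augment(img, [Box2D(0, 0, 0, 10, 20)], rot=180)
        b = mapped[0]
        assert (b.x, b.y, b.w, b.h) == (90, 80, 10, 20)

    def test_four_quarter_turns_are_identity(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(30, 50))
        boxes = [Box2D(0, 5, 3, 10, 7), Box2D(1, 20, 10, 4, 12)]
        cur_img, cur_boxes = img, boxes
        for _ in range(4):
            cur_img, cur_boxes = augment(cur_img, cur_boxes, rot=90)
        np.testing.assert_array_equal(cur_img, img)
        assert cur_boxes == boxes

    def test_double_flip_is_identity(self):
        img = np.arange(20.0).reshape(4, 5)
        boxes = [Box2D(0, 1, 1, 2, 2)]
        mid_img, mid_boxes = augment(img, boxes, flip_lr=True)
        out_img, out_boxes = augment(mid_img, mid_boxes, flip_lr=True)
        np.testing.assert_array_equal(out_img, img)
        assert out_boxes == boxes

    @pytest.mark.parametrize("rot", [90, 180, 270])
    @pytest.mark.parametrize("flip", [False, True])
    def test_boxes_track_pixels_and_iou_is_invariant(self, rot, flip):
        img = np.zeros((40, 60))
        a = Box2D(0, 10, 5, 12, 8)
        b = Box2D(0, 14, 7, 12, 8)
        img[int(a.y):int(a.y2), int(a.x):int(a.x2)] = 1.0
        out, mapped = augment(img, [a, b], rot=rot, flip_lr=flip)
        ma, mb = mapped
        # the mapped box still bounds exactly the stamped pixels
        rows = np.nonzero(out.any(axis=1))[0]
        cols = np.nonzero(out.any(axis=0))[0]
        assert (ma.x, ma.y) == (cols[0], rows[0])
        assert (ma.w, ma.h) == (len(cols), len(rows))
        assert iou(ma, mb) == pytest.approx(iou(a, b))

    def test_invalid_rotation_rejected(self):
        with pytest.raises(ValueError):
            augment(np.zeros((4, 4)), [], rot=45)


class TestAnchors:
    def test_two_distinct_sizes_recovered_exactly(self):
        boxes = [Box2D(0, 0, 0, 10, 10) for _ in range(50)] + [
            Box2D(0, 0, 0, 30, 30) for _ in range(50)
        ]
        anchors = estimate_anchors(boxes, k=2, seed=0).anchors
        np.testing.assert_allclose(anchors, [[10, 10], [30, 30]])

    def test_single_anchor_of_identical_boxes(self):
        boxes = [Box2D(0, 0, 0, 12, 12) for _ in range(10)]
        np.testing.assert_allclose(estimate_anchors(boxes, k=1).anchors, [[12, 12]])

    def test_output_size_and_order(self):
        rng = np.random.default_rng(1)
        boxes = [
            Box2D(0, 0, 0, float(w), float(h))
            for w, h in rng.integers(3, 40, size=(60, 2))
        ]
        anchors = estimate_anchors(boxes, k=7, seed=3)
        assert anchors.k == 7
        areas = anchors.anchors[:, 0] * anchors.anchors[:, 1]
        assert np.all(np.diff(areas) >= 0)

    def test_fewer_boxes_than_k_rejected(self):
        with pytest.raises(ValueError):
            estimate_anchors([Box2D(0, 0, 0, 5, 5)], k=7)


@pytest.fixture(scope="module")
def train_scans():
    scans = []
    for seed in (21, 22):
        cfg = small_config(seed=seed, n_lesions=2, n_vessels=0)
        volume, truth = generate_scan(cfg, f"train{seed}")
        mask, stripped = extract_brain(volume)
        norm = normalize_slices(stripped, mask)
        scans.append((norm, mask, link_boxes(truth.gt_boxes)))
    return scans


class TestCalibration:
    def test_single_config_grid_returns_it(self, train_scans):
        only = DetectorConfig(intensity_threshold=0.7)
        assert calibrate_detector(train_scans, [only]) == only

    def test_noise_free_calibration_reaches_full_sensitivity(self, train_scans):
        from bmdetect.evaluate import match_lesions

        best = calibrate_detector(train_scans)
        det = BlobDetector(**{k: getattr(best, k) for k in (
            "intensity_threshold", "min_area_px", "max_area_px", "min_circularity")})
        tp = fn = 0
        for norm, mask, gt in train_scans:
            counts = match_lesions(gt, link_boxes(det.predict(norm, mask)))
            tp, fn = tp + counts.tp, fn + counts.fn
        assert fn == 0 and tp == 4

    def test_calibration_is_deterministic(self, train_scans):
        assert calibrate_detector(train_scans) == calibrate_detector(train_scans)

    def test_empty_grid_rejected(self, train_scans):
        with pytest.raises(ValueError):
            calibrate_detector(train_scans, [])

    def test_estimator_wrapper_exposes_fitted_attributes(self, train_scans):
        cv = BlobDetectorCV().fit(train_scans)
        assert hasattr(cv, "best_config_")
        norm, mask, _ = train_scans[0]
        assert isinstance(cv.predict(norm, mask), list)
        assert cv.get_params()["match_iou"] == 0.5
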