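"""Detection: enhancement contract, both operators, and the merged list."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coagg import (
    DetectConfig,
    ParameterError,
    SynthFieldParams,
    detect_spots,
    detect_spots_contour,
    detect_spots_hough,
    enhance,
    generate_field,
)
from coagg.colocalization import evaluate_detections


def _render_spot(shape, cx, cy, amp=1500.0, sigma=1.5, bg=200.0):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = bg + amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2))
    return np.rint(img).astype(np.uint16)


class TestEnhance:
    def test_constant_image_stays_constant(self):
        out = enhance(np.full((40, 40), 123, dtype=np.uint16))
        assert out.dtype == np.uint8
        assert np.all(out == out.flat[0])

    def test_two_level_cdf_mapping(self):
        # 25% at the low level -> round(255*0.25)=64; high level -> 255
        img = np.zeros((10, 10), dtype=np.uint16)
        img[:, :] = 900
        img[:5, :5] = 100  # 25 of 100 pixels
        out = enhance(img)
        assert set(np.unique(out)) == {64, 255}
        assert np.all(out[img == 100] == 64)
        assert np.all(out[img == 900] == 255)

    @given(st.integers(min_value=1, max_value=1000),
           st.integers(min_value=2, max_value=7))
    def test_rank_preserving_relabel_invariance(self, scale, offset):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 300, size=(32, 32)).astype(np.int64)
        relabeled = img * scale + offset  # strictly increasing relabeling
        assert np.array_equal(enhance(img), enhance(relabeled))

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            enhance(np.empty((0, 0)))


class TestContour:
    def test_blank_image_gives_empty_list(self):
        img = np.full((64, 64), 77, dtype=np.uint16)
        assert detect_spots_contour(enhance(img)) == []

    def test_single_spot_center_within_one_px(self):
        img = _render_spot((100, 100), cx=50.0, cy=40.0)
        spots = detect_spots_contour(enhance(img))
        assert len(spots) == 1
        assert abs(spots[0].x_px - 50.0) <= 1.0
        assert abs(spots[0].y_px - 40.0) <= 1.0

    def test_two_disjoint_spots_both_found(self):
        img = _render_spot((100, 100), 30.0, 30.0).astype(float)
        img += _render_spot((100, 100), 70.0, 72.0, bg=0.0)
        spots = detect_spots_contour(enhance(np.rint(img).astype(np.uint16)))
        assert len(spots) == 2

    def test_ordering_is_row_major(self):
        img = _render_spot((100, 100), 80.0, 20.0).astype(float)
        img += _render_spot((100, 100), 20.0, 80.0, bg=0.0)
        spots = detect_spots_contour(enhance(np.rint(img).astype(np.uint16)))
        assert [round(s.y_px) for s in spots] == sorted(
            round(s.y_px) for s in spots)


class TestHough:
    def test_blank_image_gives_empty_list(self):
        img = np.full((64, 64), 500, dtype=np.uint16)
        assert detect_spots_hough(enhance(img)) == []

    def test_bright_disc_radius_recovered(self):
        h = w = 80
        yy, xx = np.mgrid[0:h, 0:w]
        img = np.full((h, w), 200.0)
        img[(xx - 40) ** 2 + (yy - 40) ** 2 <= 5 ** 2] = 2000
        rng = np.random.default_rng(1)
        img = np.rint(img + rng.normal(0, 10, img.shape)).astype(np.uint16)
        spots = detect_spots_hough(enhance(img))
        assert len(spots) >= 1
        best = min(spots, key=lambda s: (s.x_px - 40) ** 2 + (s.y_px - 40) ** 2)
        assert np.hypot(best.x_px - 40, best.y_px - 40) <= 2.0
        assert abs(best.radius_px - 5.0) <= 2.0

    def test_oversized_radius_range_rejected(self):
        cfg = DetectConfig(hough_r_min_px=2, hough_r_max_px=40)
        with pytest.raises(ParameterError, match="hough_r_max_px"):
            detect_spots_hough(np.zeros((64, 64)), cfg)


class TestMergedDetector:
    def test_determinism(self, default_field):
        fld, _ = default_field
        s1 = detect_spots(fld.red_image)
        s2 = detect_spots(fld.red_image)
        assert [(a.x_px, a.y_px, a.method) for a in s1] == \
               [(a.x_px, a.y_px, a.method) for a in s2]

    def test_min_separation_invariant(self, default_field):
        fld, _ = default_field
        cfg = DetectConfig()
        spots = detect_spots(fld.red_image, cfg)
        xy = np.array([(s.x_px, s.y_px) for s in spots])
        d = np.hypot(xy[:, None, 0] - xy[None, :, 0],
                     xy[:, None, 1] - xy[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= cfg.merge_dist_px

    def test_agreeing_detections_merge_to_one(self):
        img = _render_spot((100, 100), 50.0, 50.0)
        spots = detect_spots(img)
        assert len(spots) == 1

    def test_spots_inside_image_bounds(self, default_field):
        fld, _ = default_field
        h, w = fld.red_image.shape
        for s in detect_spots(fld.red_image):
            assert 0 <= s.x_px < w and 0 <= s.y_px < h
            assert s.radius_px > 0

    def test_blank_field_no_detections(self, blank_params):
        fld, _ = generate_field(blank_params)
        assert detect_spots(fld.red_image) == []

    def test_count_monotone_in_true_rate(self):
        # mean detected count non-decreasing in the true spot rate
        means = []
        for lam in (5.0, 20.0, 45.0):
            n = []
            for seed in range(6):
                p = SynthFieldParams(width_px=256, height_px=256,
                                     lambda_pair=0, lambda_red_only=lam,
                                     lambda_blue_only=0, seed=seed)
                fld, _ = generate_field(p)
                n.append(len(detect_spots(fld.red_image)))
            means.append(np.mean(n))
        assert means[0] <= means[1] <= means[2]

    def test_recall_precision_on_synthetic_fields(self):
        # spot check ahead of the full 50-field suite in acceptance tests
        recs, precs = [], []
        for seed in range(6):
            fld, truth = generate_field(SynthFieldParams(seed=seed))
            r, p, _ = evaluate_detections(
                detect_spots(fld.red_image), truth.red_centers, 2.0)
            recs.append(r)
            precs.append(p)
        assert np.mean(recs) >= 0.9
        assert np.mean(precs) >= 0.9
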