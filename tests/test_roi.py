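"""Pleural-line and rib-shadow detection, band geometry, manual ROI import."""

import json

import numpy as np
import pytest

from greylung.errors import (DetectionError, FormatError, GeometryError,
                             ValidationError)
from greylung.roi import (PleuralROI, build_roi, detect_pleural_line,
                          detect_rib_shadows, detect_roi, import_manual_roi,
                          load_frame)
from greylung.synth import render_frame


class TestDetectPleuralLine:
    def test_recovers_constructed_bright_row(self, make_frame):
        img = np.full((200, 100), 20, dtype=np.uint8)
        img[120, :] = 240
        frame = make_frame(img)
        # oracle: exhaustive row-mean scan
        oracle = int(np.argmax(img.mean(axis=1)))
        assert oracle == 120
        assert detect_pleural_line(frame, smooth_rows=1) == 120

    def test_tie_breaks_to_shallower_row(self, make_frame):
        img = np.full((50, 40), 10, dtype=np.uint8)
        img[12, :] = 200
        img[30, :] = 200
        assert detect_pleural_line(make_frame(img), smooth_rows=1) == 12

    def test_flat_image_is_detection_failure(self, make_frame):
        with pytest.raises(DetectionError):
            detect_pleural_line(make_frame(np.full((50, 40), 77)))

    def test_search_band_restricts_result(self, make_frame):
        img = np.full((100, 40), 10, dtype=np.uint8)
        img[10, :] = 250
        img[60, :] = 200
        assert detect_pleural_line(make_frame(img), search_band=(40, 100),
                                   smooth_rows=1) == 60


class TestDetectRibShadows:
    def make_shadowed(self, width=200, left=20, right=180):
        img = np.full((100, width), 100, dtype=np.uint8)
        img[:, :left] = 2
        img[:, right:] = 2
        return img

    def test_recovers_constructed_shadow_bounds(self, make_frame):
        img = self.make_shadowed()
        frame = make_frame(img)
        # oracle: exhaustive column-mean scan against the threshold
        col_means = img[0:, :].mean(axis=0)
        thr = 0.35 * np.median(img)
        assert (int(np.argmax(col_means >= thr)),
                int(len(col_means) - 1 - np.argmax(col_means[::-1] >= thr))) \
            == (20, 179)
        assert detect_rib_shadows(frame, pleural_row=0) == (20, 179)

    def test_no_shadow_falls_back_to_edges_with_warning(self, make_frame):
        frame = make_frame(np.full((60, 80), 100))
        with pytest.warns(UserWarning, match="no rib shadow"):
            assert detect_rib_shadows(frame, pleural_row=0) == (0, 79)

    def test_all_dark_image_fails(self, make_frame):
        img = np.zeros((60, 80), dtype=np.uint8)
        img[0, 0] = 255  # non-flat, but every column below threshold
        with pytest.raises(DetectionError):
            detect_rib_shadows(make_frame(img), pleural_row=0)


class TestBuildROI:
    def test_default_calibration_gives_50px_band(self, make_frame):
        frame = make_frame(np.zeros((200, 100)), spacing=0.02)
        roi = build_roi(frame, pleural_row=10, left_col=5, right_col=90,
                        depth_mm=1.0)
        assert roi.depth_px == 50

    def test_mask_count_is_depth_times_width(self, make_frame):
        frame = make_frame(np.zeros((200, 120)))
        roi = build_roi(frame, 0, 10, 109)
        assert roi.n_pixels == 50 * 100 == roi.depth_px * roi.width

    def test_band_off_bottom_is_geometry_error(self, make_frame):
        frame = make_frame(np.zeros((60, 100)))
        with pytest.raises(GeometryError):
            build_roi(frame, pleural_row=55, left_col=0, right_col=99)

    def test_small_overhang_clips_with_warning(self, make_frame):
        frame = make_frame(np.zeros((200, 100)))
        with pytest.warns(UserWarning, match="clipped"):
            roi = build_roi(frame, pleural_row=153, left_col=0, right_col=99)
        assert roi.depth_px == 47


class TestManualROI:
    def test_bounds_json_round_trips_to_band(self, tmp_path, make_frame):
        frame = make_frame(np.zeros((200, 120)))
        built = build_roi(frame, 30, 10, 109)
        path = tmp_path / "roi.json"
        built.save(path)
        loaded = import_manual_roi(path, image_shape=frame.shape)
        assert np.array_equal(loaded.mask, built.mask)

    def test_polygon_covering_band_matches_mask_count(self, tmp_path):
        # rectangle rows [30, 79], cols [10, 109]: same band as bounds form
        poly = [[30, 10], [30, 109], [79, 109], [79, 10]]
        path = tmp_path / "poly.json"
        path.write_text(json.dumps({"polygon": poly}))
        roi = import_manual_roi(path, image_shape=(200, 120))
        # oracle: rasterisation of an axis-aligned rectangle is its area
        assert roi.n_pixels == 50 * 100

    def test_negative_coordinates_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"pleural_row": -1, "left_col": 0,
                                    "right_col": 10, "depth_px": 5}))
        with pytest.raises(ValidationError):
            import_manual_roi(path)

    def test_malformed_json_rejected(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text("{not json")
        with pytest.raises(ValidationError):
            import_manual_roi(path)


class TestLoadFrame:
    def test_valid_png_round_trip(self, tmp_path):
        import imageio.v3 as iio
        img = np.arange(0, 250, dtype=np.uint8).reshape(25, 10)
        iio.imwrite(tmp_path / "f.png", img)
        frame = load_frame(tmp_path / "f.png")
        assert frame.pixels.max() <= 255
        assert np.array_equal(frame.pixels, img)

    def test_rgb_without_flag_is_format_error(self, tmp_path):
        import imageio.v3 as iio
        rgb = np.zeros((10, 10, 3), dtype=np.uint8)
        rgb[..., 0] = 200
        iio.imwrite(tmp_path / "rgb.png", rgb)
        with pytest.raises(FormatError):
            load_frame(tmp_path / "rgb.png")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_frame(tmp_path / "absent.png")


class TestOnSyntheticFrames:
    def test_noiseless_detection_is_exact(self, noiseless_truth):
        for pressure in (0, 15, 35):
            frame_sim = render_frame(noiseless_truth, pressure, "inflation",
                                     rng=0)
            from greylung.roi import ImageFrame
            frame = ImageFrame(frame_sim.pixels,
                               pixel_spacing_mm=frame_sim.pixel_spacing_mm)
            assert detect_pleural_line(frame) == frame_sim.pleural_row_truth
            left, right = detect_rib_shadows(frame, frame_sim.pleural_row_truth)
            (l0, l1), (r0, r1) = frame_sim.shadow_cols_truth
            assert (left, right) == (l1 + 1, r0 - 1)

    def test_noisy_detection_within_two_rows_95pct(self, make_truth):
        from dataclasses import replace as _  # noqa: F401
        from greylung.roi import ImageFrame
        hits = 0
        n = 200
        for seed in range(n):
            t = make_truth(noise_sigma=10.0, echo_baseline=60, echo_gain=10,
                           seed=seed)
            sim = render_frame(t, 25, "inflation", rng=seed)
            frame = ImageFrame(sim.pixels, pixel_spacing_mm=sim.pixel_spacing_mm)
            if abs(detect_pleural_line(frame) - sim.pleural_row_truth) <= 2:
                hits += 1
        assert hits / n >= 0.95

    def test_detection_invariant_to_positive_rescale(self, noiseless_truth):
        from greylung.roi import ImageFrame
        sim = render_frame(noiseless_truth, 20, "inflation", rng=0)
        full = ImageFrame(sim.pixels, pixel_spacing_mm=sim.pixel_spacing_mm)
        halved = ImageFrame((sim.pixels // 2).astype(np.uint8),
                            pixel_spacing_mm=sim.pixel_spacing_mm)
        roi_a = detect_roi(full)
        roi_b = detect_roi(halved)
        assert (roi_a.pleural_row, roi_a.left_col, roi_a.right_col) == \
               (roi_b.pleural_row, roi_b.left_col, roi_b.right_col)

    def test_manual_equals_automatic_for_same_bounds(self, tmp_path,
                                                     noiseless_truth):
        from greylung.roi import ImageFrame
        sim = render_frame(noiseless_truth, 20, "inflation", rng=0)
        frame = ImageFrame(sim.pixels, pixel_spacing_mm=sim.pixel_spacing_mm)
        auto = detect_roi(frame)
        path = tmp_path / "m.json"
        auto.save(path)
        manual = import_manual_roi(path, image_shape=frame.shape)
        assert np.array_equal(auto.mask, manual.mask)


class TestPleuralROIInvariants:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValidationError):
            PleuralROI(pleural_row=0, left_col=10, right_col=5, depth_px=50,
                       mask=np.zeros((60, 20), dtype=bool))
        with pytest.raises(ValidationError):
            PleuralROI.band(0, 5, 10, 0, (60, 20))

    def test_band_outside_image_rejected(self):
        with pytest.raises(GeometryError):
            PleuralROI.band(20, 0, 30, 50, (60, 20))
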