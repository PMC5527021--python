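"""Image-quantification stage: alignment, segmentation rules, measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimevolve import spotquant, synthetic
from mimevolve.spotquant import (
    DegenerateGeometryError,
    LandmarkPair,
    SegmentationConfig,
    ThresholdSpec,
    WingImage,
    align_wing,
    analysis_region,
    grey_convert,
    measure,
    segment_distinct,
    segment_fused,
    wing_mask,
)


def _flat_image(h, w, colour):
    px = np.zeros((h, w, 3), np.uint8)
    px[:] = colour
    return WingImage(px)


class TestGreyConvert:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((255, 255, 255), 255.0), ((0, 0, 0), 0.0), ((100, 200, 50), 153.0)],
    )
    def test_luma_weights(self, rgb, expected):
        # 0.299 R + 0.587 G + 0.114 B by hand
        img = _flat_image(2, 2, rgb)
        assert grey_convert(img)[0, 0] == pytest.approx(expected, abs=1e-9)


class TestAlignWing:
    def test_already_vertical_is_identity(self):
        img = _flat_image(120, 100, (10, 10, 10))
        img.pixels[40:90, 45:55] = 200
        aligned, lm = align_wing(img, LandmarkPair((50, 40), (50, 90)))
        assert aligned.pixels.shape == img.pixels.shape
        np.testing.assert_array_equal(aligned.pixels, img.pixels)
        assert lm.landmark1 == pytest.approx((50, 40))

    def test_rotated_render_becomes_vertical(self, rendered_wing_rotated):
        img, truth = rendered_wing_rotated
        _, lm = align_wing(img, LandmarkPair(truth.landmark1, truth.landmark2))
        assert abs(lm.landmark1[0] - lm.landmark2[0]) < 0.5
        assert lm.landmark2[1] > lm.landmark1[1]

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            LandmarkPair((10, 10), (10, 10))

    def test_no_wing_pixel_lost(self, rendered_wing_rotated):
        img, truth = rendered_wing_rotated
        aligned, _ = align_wing(img, LandmarkPair(truth.landmark1, truth.landmark2))
        # non-background pixel counts agree to within the interpolation rim
        bg = np.array([0, 162, 255])
        before = (np.abs(img.pixels.astype(int) - bg).max(axis=2) > 60).sum()
        after = (np.abs(aligned.pixels.astype(int) - bg).max(axis=2) > 60).sum()
        assert after >= before * 0.99


class TestWingMask:
    def test_recovers_ground_truth(self, rendered_wing):
        img, truth = rendered_wing
        wm = wing_mask(img, LandmarkPair(truth.landmark1, truth.landmark2))
        assert (wm == truth.wing_mask).mean() >= 0.995

    def test_uniform_image_errors(self):
        img = _flat_image(50, 50, (90, 90, 90))
        with pytest.raises(ValueError):
            wing_mask(img, LandmarkPair((20, 20), (20, 40)))


class TestAnalysisRegion:
    def test_matches_renderer_row_filter(self, rendered_wing):
        img, truth = rendered_wing
        lm = LandmarkPair(truth.landmark1, truth.landmark2)
        region = analysis_region(img, lm, truth.wing_mask)
        assert region.sum() == truth.analysis_mask.sum()

    def test_landmark_at_top_keeps_whole_wing(self, rendered_wing):
        img, truth = rendered_wing
        lm = LandmarkPair((truth.landmark1[0], 0.0), truth.landmark2)
        region = analysis_region(img, lm, truth.wing_mask)
        assert region.sum() == truth.wing_mask.sum()

    def test_landmark_below_wing_is_empty(self, rendered_wing):
        img, truth = rendered_wing
        h = img.pixels.shape[0]
        lm = LandmarkPair((truth.landmark1[0], h - 1.0), (truth.landmark2[0] + 5, h - 1.0))
        with pytest.raises(DegenerateGeometryError):
            analysis_region(img, lm, truth.wing_mask)


class TestSegmentDistinct:
    def test_pure_white_spot_on_black_wing(self):
        img = _flat_image(40, 40, (20, 20, 20))
        img.pixels[10:20, 10:20] = 255
        region = np.ones((40, 40), bool)
        white, red = segment_distinct(img, region)
        assert white[10:20, 10:20].all() and white.sum() == 100
        assert not red.any()

    def test_red_spot_by_dominance_margin(self):
        img = _flat_image(40, 40, (20, 20, 20))
        img.pixels[5:10, 5:10] = (200, 30, 30)
        region = np.ones((40, 40), bool)
        white, red = segment_distinct(img, region)
        assert red[5:10, 5:10].all() and red.sum() == 25
        assert not white.any()

    def test_matches_renderer_ground_truth(self, rendered_wing):
        img, truth = rendered_wing
        lm = LandmarkPair(truth.landmark1, truth.landmark2)
        region = analysis_region(img, lm, truth.wing_mask)
        white, _ = segment_distinct(img, region)
        measured = white.sum() / region.sum()
        assert abs(measured - truth.true_white_fraction) < 0.005


class TestSegmentFused:
    def _sample_image(self, values):
        """A 1xN strip image whose grey levels equal ``values``."""
        n = len(values)
        px = np.zeros((3, n, 3), np.uint8)
        px[1, :, :] = np.array(values, np.uint8)[:, None]
        return WingImage(px), np.array([[False] * n, [True] * n, [False] * n])

    def test_mean_minus_sd_rule_arithmetic(self):
        img, region = self._sample_image([200, 210, 220, 201, 200])
        tspec = ThresholdSpec(sampled_points=[(0, 1), (1, 1), (2, 1)], n_sample_points=3)
        white, threshold = segment_fused(img, region, tspec)
        assert threshold == pytest.approx(200.0)  # mean 210, SD 10
        # pixel at 201 included, pixels at 200 excluded (strict inequality)
        assert white[1, 3] and not white[1, 0] and not white[1, 4]

    def test_degenerate_zero_sd_excludes_boundary(self):
        img, region = self._sample_image([210, 210, 210, 211])
        tspec = ThresholdSpec(sampled_points=[(0, 1), (1, 1), (2, 1)], n_sample_points=3)
        with pytest.warns(UserWarning, match="SD = 0"):
            white, threshold = segment_fused(img, region, tspec)
        assert threshold == pytest.approx(210.0)
        assert not white[1, 0] and white[1, 3]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSpec(sampled_points=[(0, 1)])

    def test_agrees_with_distinct_rule_on_unfused_render(self):
        spec = synthetic.WingRenderSpec(
            target_white_fraction=0.08, fused=False, rotation_deg=0.0, seed=9
        )
        img, truth = synthetic.render_wing(spec)
        lm = LandmarkPair(truth.landmark1, truth.landmark2)
        m_distinct = measure(img, lm)
        m_fused = measure(img, lm, tspec=ThresholdSpec(seed=11))
        assert m_fused.white_area_px == pytest.approx(m_distinct.white_area_px, rel=0.01)

    def test_fused_render_measured_against_unfused_twin(self):
        kw = dict(target_white_fraction=0.08, rotation_deg=0.0, seed=9)
        img_f, truth_f = synthetic.render_wing(synthetic.WingRenderSpec(fused=True, **kw))
        img_u, _ = synthetic.render_wing(synthetic.WingRenderSpec(fused=False, **kw))
        lm = LandmarkPair(truth_f.landmark1, truth_f.landmark2)
        m_f = measure(img_f, lm, tspec=ThresholdSpec(seed=11))
        m_u = measure(img_u, lm)
        assert m_f.white_area_px == pytest.approx(m_u.white_area_px, rel=0.01)

    @given(st.integers(0, 254))
    @settings(max_examples=25, deadline=None)
    def test_lowering_threshold_never_shrinks_mask(self, cut):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 256, size=(20, 20, 3)).astype(np.uint8)
        img = WingImage(px)
        region = np.ones((20, 20), bool)
        grey = grey_convert(img)
        hi = region & (grey > cut + 1)
        lo = region & (grey > cut)
        assert (hi <= lo).all()


class TestMeasure:
    def test_simple_ratio(self):
        m = spotquant.SpotMeasurement(100, 0, 1000, 0.10, 0.0, "distinct")
        assert m.white_rel == pytest.approx(m.white_area_px / m.wing_area_px)

    def test_no_spots_measures_zero(self):
        spec = synthetic.WingRenderSpec(
            target_white_fraction=0.0, n_red_spots=0, seed=2
        )
        img, truth = synthetic.render_wing(spec)
        m = measure(img, LandmarkPair(truth.landmark1, truth.landmark2))
        assert m.white_rel == 0.0 and m.red_rel == 0.0

    def test_accuracy_over_fraction_range(self):
        errors = []
        for i, frac in enumerate(np.linspace(0.02, 0.12, 8)):
            spec = synthetic.WingRenderSpec(
                target_white_fraction=float(frac), rotation_deg=(11.0 * i) % 35, seed=20 + i
            )
            img, truth = synthetic.render_wing(spec)
            m = measure(img, LandmarkPair(truth.landmark1, truth.landmark2))
            errors.append(abs(m.white_rel - truth.true_white_fraction))
        assert float(np.mean(errors)) < 0.005

    def test_scale_invariance(self, rendered_wing):
        img, truth = rendered_wing
        lm = LandmarkPair(truth.landmark1, truth.landmark2)
        m1 = measure(img, lm)
        up = WingImage(np.kron(img.pixels, np.ones((2, 2, 1), np.uint8)))
        lm2 = LandmarkPair(
            (2 * truth.landmark1[0], 2 * truth.landmark1[1]),
            (2 * truth.landmark2[0], 2 * truth.landmark2[1]),
        )
        m2 = measure(up, lm2)
        assert abs(m1.white_rel - m2.white_rel) < 0.005

    def test_rotation_invariance(self, rendered_wing, rendered_wing_rotated):
        m = []
        for img, truth in (rendered_wing, rendered_wing_rotated):
            m.append(measure(img, LandmarkPair(truth.landmark1, truth.landmark2)).white_rel)
        assert abs(m[0] - m[1]) < 0.005

    def test_deterministic_with_fixed_seed(self, rendered_wing):
        img, truth = rendered_wing
        lm = LandmarkPair(truth.landmark1, truth.landmark2)
        a = measure(img, lm, tspec=ThresholdSpec(seed=5))
        b = measure(img, lm, tspec=ThresholdSpec(seed=5))
        assert a == b
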