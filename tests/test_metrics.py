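"""Choroid thickness/area/vascular-index derivation tests."""

import math

import numpy as np
import pytest

from choroidpipe.core import BScan, ScanType, SegmentationOutput, UndefinedMetricError
from choroidpipe.metrics import (
    Boundaries,
    ROIWindow,
    analyze_scan,
    compute_area,
    compute_thickness,
    compute_vascular_index,
    define_roi,
    extract_boundaries,
)
from choroidpipe.synthetic import degrade_to_probability_maps

from conftest import make_phantom


def flat_band_mask(shape=(256, 256), top=100, bottom=200):
    mask = np.zeros(shape, bool)
    mask[top:bottom, :] = True
    return mask


def sheared_band_mask(tilt_deg, thickness_um, scale=10.0, width=512, height=400,
                      top0=50.0):
    """Straight band whose locally perpendicular thickness is ``thickness_um``."""
    slope = math.tan(math.radians(tilt_deg))
    vertical_px = thickness_um / (scale * math.cos(math.radians(tilt_deg)))
    mask = np.zeros((height, width), bool)
    n = int(round(vertical_px))
    for c in range(width):
        t = int(round(top0 + slope * c))
        mask[t : t + n, c] = True
    return mask


class TestExtractBoundaries:
    def test_half_pixel_convention(self):
        b = extract_boundaries(flat_band_mask())
        assert np.all(b.upper[b.valid_columns] == 99.5)
        assert np.all(b.lower[b.valid_columns] == 199.5)

    def test_isolated_speck_ignored(self):
        mask = flat_band_mask()
        mask[10, 50] = True  # speck above the band
        b = extract_boundaries(mask)
        assert np.all(b.upper[b.valid_columns] == 99.5)

    def test_empty_columns_excluded(self):
        mask = flat_band_mask()
        mask[:, 37] = False
        b = extract_boundaries(mask)
        assert 37 not in b.valid_columns
        assert np.isnan(b.upper[37])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_boundaries(np.zeros((8, 8), bool))


class TestDefineROI:
    def test_heidelberg_example(self):
        roi = define_roi(384, 9000.0 / 768.0, 768)
        assert (roi.col_lo, roi.col_hi) == (128, 640)

    def test_clipping_at_image_edge(self):
        roi = define_roi(50, 10.0, 768)
        assert roi.col_lo == 0
        assert roi.col_hi == 350

    def test_volume_scan_centred_at_middle_column(self):
        roi = define_roi(None, 10.0, 768, scan_type="volume")
        assert roi.center_col == 384

    def test_physical_width_bounded(self):
        scale = 11.72
        roi = define_roi(384, scale, 768)
        assert (roi.col_hi - roi.col_lo) * scale <= 6000 + scale


class TestComputeThickness:
    def test_flat_band_exact(self):
        b = extract_boundaries(flat_band_mask())
        roi = ROIWindow(128, 3000.0, 28, 228)
        th = compute_thickness(b, roi, 10.0, 10.0)
        assert np.allclose(th, 1000.0, atol=1e-6)

    @pytest.mark.parametrize("tilt", [10.0, 20.0, 25.0])
    def test_sheared_band_recovers_perpendicular_truth(self, tilt):
        mask = sheared_band_mask(tilt, 1000.0)
        b = extract_boundaries(mask)
        roi = ROIWindow(256, 3000.0, 100, 400)
        th = compute_thickness(b, roi, 10.0, 10.0)
        assert np.all(np.abs(np.array(th) - 1000.0) <= 20.0)  # within 2%

    def test_zero_height_column_yields_zero(self):
        w = 64
        upper = np.full(w, 50.0)
        lower = np.full(w, 50.0)
        b = Boundaries(upper=upper, lower=lower, valid_columns=np.arange(w),
                       upper_smooth=upper, lower_smooth=lower)
        th = compute_thickness(b, ROIWindow(32, 100.0, 16, 48), 10.0, 10.0)
        assert np.allclose(th, 0.0)


class TestComputeArea:
    def test_pixel_counting_example(self):
        mask = np.zeros((300, 700), bool)
        mask[50:150, :] = True  # 100-px band
        roi = ROIWindow(350, 3000.0, 50, 649)  # 600 columns
        assert compute_area(mask, roi, 10.0, 10.0) == pytest.approx(6.0)

    def test_empty_region(self):
        roi = ROIWindow(10, 100.0, 0, 20)
        assert compute_area(np.zeros((32, 32), bool), roi, 10, 10) == 0.0

    def test_linear_in_scale(self):
        mask = flat_band_mask()
        roi = ROIWindow(128, 3000.0, 28, 228)
        a1 = compute_area(mask, roi, 10.0, 10.0)
        a2 = compute_area(mask, roi, 10.0, 20.0)
        assert a2 == pytest.approx(2 * a1)


class TestVascularIndex:
    def test_half_vessels_gives_half(self):
        region = np.ones((40, 40))
        vessel = np.zeros((40, 40))
        vessel[:20] = 1.0
        roi = ROIWindow(20, 200.0, 0, 39)
        assert compute_vascular_index(region, vessel, roi, "hard") == 0.5
        assert compute_vascular_index(region, vessel, roi, "soft") == 0.5

    def test_soft_equals_hard_on_binary_maps(self):
        rng = np.random.default_rng(0)
        region = (rng.random((64, 64)) > 0.3).astype(float)
        vessel = ((rng.random((64, 64)) > 0.6).astype(float)) * region
        roi = ROIWindow(32, 320.0, 0, 63)
        hard = compute_vascular_index(region, vessel, roi, "hard")
        soft = compute_vascular_index(region, vessel, roi, "soft")
        assert soft == pytest.approx(hard, abs=1e-12)

    def test_counting_case(self):
        rng = np.random.default_rng(1)
        region = np.ones((100, 100))
        vessel = np.zeros(10000)
        idx = rng.choice(10000, 3700, replace=False)
        vessel[idx] = 1.0
        vessel = vessel.reshape(100, 100)
        roi = ROIWindow(50, 500.0, 0, 99)
        assert compute_vascular_index(region, vessel, roi, "hard") == pytest.approx(0.37)

    def test_literal_vessel_to_nonvessel_ratio(self):
        region = np.ones((10, 10))
        vessel = np.zeros((10, 10))
        vessel[:5] = 1.0
        roi = ROIWindow(5, 50.0, 0, 9)
        literal = compute_vascular_index(region, vessel, roi, "hard",
                                         literal_ratio=True)
        assert literal == pytest.approx(1.0)  # 50 vessel / 50 non-vessel

    def test_empty_region_rejected(self):
        roi = ROIWindow(5, 50.0, 0, 9)
        with pytest.raises(UndefinedMetricError):
            compute_vascular_index(np.zeros((10, 10)), np.zeros((10, 10)), roi)

    def test_soft_converges_to_hard_under_sharpening(self):
        rng = np.random.default_rng(2)
        region = np.clip(rng.normal(0.7, 0.2, (64, 64)), 0, 1)
        vessel = np.clip(rng.normal(0.5, 0.25, (64, 64)), 0, 1)
        roi = ROIWindow(32, 320.0, 0, 63)
        hard = compute_vascular_index(region, vessel, roi, "hard")

        def sharpen(p, power):
            return p**power / (p**power + (1 - p) ** power)

        gaps = []
        for power in (1, 4, 16, 64, 256):
            soft = compute_vascular_index(
                sharpen(region, power), sharpen(vessel, power), roi, "soft"
            )
            gaps.append(abs(soft - hard))
        assert all(b <= a + 1e-9 for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] <= 0.01


class TestAnalyzeScan:
    def test_clean_synthetic_recovery(self):
        s = make_phantom(seed=3, speckle=0.0, choroid_thickness_variation=0.0)
        seg = degrade_to_probability_maps(s, 0.0, 0.0, seed=0)
        bscan = BScan(s.image, s.scale_x, s.scale_y)
        m = analyze_scan(bscan, seg)
        assert m.fovea_col == s.fovea_col
        assert abs(m.thickness_mean_um - 800.0) <= 0.02 * 800.0
        lo, hi = m.roi.col_lo, m.roi.col_hi
        expected_area = (
            s.region_mask[:, lo : hi + 1].sum() * s.scale_x * s.scale_y * 1e-6
        )
        assert m.area_mm2 == pytest.approx(expected_area, rel=1e-12)
        planted = (
            s.vessel_mask[:, lo : hi + 1].sum() / s.region_mask[:, lo : hi + 1].sum()
        )
        assert abs(m.cvi - planted) <= 0.02
        assert abs(m.soft_cvi - m.cvi) <= 1e-12

    def test_peripapillary_returns_masks_only(self):
        s = make_phantom(seed=4, speckle=0.0)
        seg = degrade_to_probability_maps(s, 0.0, 0.0, seed=0)
        bscan = BScan(s.image, s.scale_x, s.scale_y,
                      scan_type=ScanType.PERIPAPILLARY)
        m = analyze_scan(bscan, seg)
        assert np.isnan(m.area_mm2) and np.isnan(m.cvi)
        assert m.roi is None
        assert m.region_mask is not None and m.region_mask.any()
        assert "peripapillary" in m.flags[0]

    def test_subthreshold_region_map_raises(self):
        s = make_phantom(seed=5, speckle=0.0)
        seg = SegmentationOutput(
            region_prob=np.full(s.shape, 0.49),
            vessel_prob=np.zeros(s.shape),
            fovea_prob=degrade_to_probability_maps(s, 0, 0, 0).fovea_prob,
        )
        with pytest.raises(UndefinedMetricError):
            analyze_scan(BScan(s.image, s.scale_x, s.scale_y), seg)

    def test_no_fovea_falls_back_to_centre(self):
        s = make_phantom(seed=6, speckle=0.0)
        seg = SegmentationOutput(
            region_prob=s.region_mask.astype(float),
            vessel_prob=s.vessel_mask.astype(float),
            fovea_prob=np.zeros(s.shape),
        )
        with pytest.warns(UserWarning, match="centre column"):
            m = analyze_scan(BScan(s.image, s.scale_x, s.scale_y), seg)
        assert m.fovea_col == s.shape[1] // 2
        assert "fovea-fallback-center" in m.flags

    def test_unit_consistency_under_resampling(self):
        s = make_phantom(seed=7, speckle=0.0, choroid_thickness_variation=0.0)
        seg = degrade_to_probability_maps(s, 0.0, 0.0, seed=0)
        m1 = analyze_scan(BScan(s.image, s.scale_x, s.scale_y), seg)

        up = lambda a: np.repeat(np.repeat(a, 2, axis=0), 2, axis=1)  # noqa: E731
        s2 = make_phantom(seed=7, speckle=0.0, choroid_thickness_variation=0.0)
        seg2 = SegmentationOutput(
            region_prob=up(seg.region_prob),
            vessel_prob=up(seg.vessel_prob),
            fovea_prob=up(seg.fovea_prob),
        )
        m2 = analyze_scan(
            BScan(up(s2.image), s2.scale_x / 2, s2.scale_y / 2), seg2
        )
        assert m2.area_mm2 == pytest.approx(m1.area_mm2, rel=0.01)
        assert m2.thickness_mean_um == pytest.approx(m1.thickness_mean_um, rel=0.01)
        assert m2.cvi == pytest.approx(m1.cvi, abs=0.01)
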