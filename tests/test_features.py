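import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tendonqus.features import (
    FeatureConfig,
    LONGITUDINAL_FEATURES,
    TRANSVERSE_FEATURES,
    cooccurrence_matrix,
    extract_features,
    first_order_stats,
    longitudinal_thickness,
    texture_features,
    transverse_geometry,
)
from tendonqus.roi_io import PixelMask, RegionOfInterest, ROIError

from ._oracles import moments, texture_by_enumeration
from .conftest import make_image


def band(upper, lower):
    return RegionOfInterest(
        kind="band", view="longitudinal",
        upper_edge=np.asarray(upper, float), lower_edge=np.asarray(lower, float),
    )


def full_mask(shape):
    return PixelMask(mask=np.ones(shape, dtype=bool))


class TestLongitudinalThickness:
    def test_parallel_edges(self, cal_01mm):
        roi = band([[0, 10], [50, 10]], [[0, 30], [50, 30]])
        assert longitudinal_thickness(roi, cal_01mm) == pytest.approx(0.20)

    def test_wedge_matches_brute_force(self, cal_01mm):
        roi = band([[0, 10], [40, 10]], [[0, 20], [40, 40]])
        # oracle: average the 100 interpolated pair distances directly
        xs = np.linspace(0, 40, 100)
        dist = (20 + xs / 40 * 20) - 10.0
        expected_cm = dist.mean() * 0.1 / 10.0
        got = longitudinal_thickness(roi, cal_01mm)
        assert got == pytest.approx(expected_cm, abs=1e-9)

    def test_disjoint_x_ranges_error(self):
        with pytest.raises(ROIError):
            band([[0, 10], [10, 10]], [[20, 30], [30, 30]])

    def test_n_points_insensitive_for_linear_edges(self, cal_01mm):
        roi = band([[0, 10], [40, 12]], [[0, 30], [40, 36]])
        t100 = longitudinal_thickness(roi, cal_01mm, n_points=100)
        t1000 = longitudinal_thickness(roi, cal_01mm, n_points=1000)
        assert t100 == pytest.approx(t1000, rel=1e-3)


class TestTransverseGeometry:
    def test_rectangle_closed_form(self, cal_01mm):
        verts = np.array([[0, 0], [100, 0], [100, 40], [0, 40]], float)
        roi = RegionOfInterest(kind="contour", view="transverse", contour=verts)
        t, w, a = transverse_geometry(roi, cal_01mm)
        assert (t, w) == (pytest.approx(0.40), pytest.approx(1.00))
        assert a == pytest.approx(0.40)

    def test_polygon_ellipse_area_vs_closed_form(self, cal_01mm):
        theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        verts = np.column_stack([80 + 60 * np.cos(theta), 40 + 25 * np.sin(theta)])
        roi = RegionOfInterest(kind="contour", view="transverse", contour=verts)
        _, _, area = transverse_geometry(roi, cal_01mm)
        assert area == pytest.approx(math.pi * 60 * 25 * 0.01 / 100.0, rel=1e-3)
        assert area == pytest.approx(0.4712, abs=5e-4)

    def test_orientation_invariance(self, cal_01mm):
        verts = np.array([[0, 0], [30, 5], [25, 20], [3, 18]], float)
        roi_ccw = RegionOfInterest(kind="contour", view="transverse", contour=verts)
        roi_cw = RegionOfInterest(kind="contour", view="transverse", contour=verts[::-1])
        assert transverse_geometry(roi_ccw, cal_01mm) == transverse_geometry(roi_cw, cal_01mm)


class TestFirstOrderStats:
    def test_constant_roi(self):
        img = make_image(np.full((10, 10), 100))
        mean, var, skew, kurt, ent = first_order_stats(img, full_mask((10, 10)))
        assert (mean, var, ent) == (100.0, 0.0, 0.0)
        assert math.isnan(skew) and math.isnan(kurt)

    def test_two_point_distribution(self):
        px = np.zeros((10, 10), int)
        px[:5] = 255
        img = make_image(px)
        mean, var, skew, kurt, ent = first_order_stats(img, full_mask((10, 10)))
        assert mean == pytest.approx(127.5)
        assert var == pytest.approx(16256.25)
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert kurt == pytest.approx(1.0)
        assert ent == pytest.approx(1.0)

    def test_empty_mask_errors(self):
        img = make_image(np.zeros((5, 5), int))
        with pytest.raises(ValueError):
            first_order_stats(img, PixelMask(mask=np.zeros((5, 5), bool)))

    def test_matches_naive_loop_oracle(self, rng):
        for _ in range(100):
            px = rng.integers(0, 256, (12, 12))
            m = rng.random((12, 12)) < 0.6
            if not m.any():
                m[0, 0] = True
            img = make_image(px)
            got = first_order_stats(img, PixelMask(mask=m))
            exp = moments(px[m])
            for g, e in zip(got, exp):
                if math.isnan(e):
                    assert math.isnan(g)
                else:
                    assert g == pytest.approx(e, rel=1e-9, abs=1e-9)

    def test_intensity_shift_property(self, rng):
        px = rng.integers(40, 200, (20, 20))
        img = make_image(px)
        shifted = make_image(px + 30)
        m = full_mask((20, 20))
        base = first_order_stats(img, m)
        moved = first_order_stats(shifted, m)
        assert moved[0] == pytest.approx(base[0] + 30)
        for k in (1, 2, 3):
            assert moved[k] == pytest.approx(base[k], rel=1e-12)


class TestCooccurrence:
    def test_constant_2x2(self):
        img = make_image(np.zeros((2, 2), int))
        glcm = cooccurrence_matrix(img, full_mask((2, 2)), d=1, angle_deg=0)
        assert glcm.p[0, 0] == pytest.approx(1.0)
        assert glcm.pair_count == 4  # 2 ordered pairs, doubled by symmetry

    def test_alternating_row(self):
        img = make_image(np.array([[0, 255, 0, 255]]))
        glcm = cooccurrence_matrix(img, full_mask((1, 4)), d=1, angle_deg=0)
        assert glcm.p[0, 255] == pytest.approx(0.5)
        assert glcm.p[255, 0] == pytest.approx(0.5)

    def test_masked_middle_no_pairs(self):
        img = make_image(np.array([[1, 2, 3]]))
        m = np.array([[True, False, True]])
        with pytest.raises(ValueError, match="no co-occurring"):
            cooccurrence_matrix(img, PixelMask(mask=m), d=1, angle_deg=0)

    def test_offset_too_large_errors(self):
        img = make_image(np.zeros((3, 3), int))
        with pytest.raises(ValueError):
            cooccurrence_matrix(img, full_mask((3, 3)), d=10, angle_deg=0)

    def test_symmetry_and_normalization(self, rng):
        px = rng.integers(0, 256, (15, 15))
        img = make_image(px)
        for angle in (0, 45, 90, 135):
            glcm = cooccurrence_matrix(img, full_mask((15, 15)), d=3, angle_deg=angle)
            assert glcm.p.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(glcm.p, glcm.p.T)


class TestTextureFeatures:
    def test_constant_image_limits(self):
        img = make_image(np.full((8, 8), 42))
        con, eng, hmg, ent, _ = texture_features(img, full_mask((8, 8)), d=1)
        assert (con, eng, hmg, ent) == (0.0, 1.0, 1.0, 0.0)

    def test_two_point_closed_form(self):
        # vertical stripes 0/255 of width 1 at d=1, 0 deg: all pairs are (0,255)/(255,0)
        px = np.tile(np.array([0, 255]), (4, 4))
        img = make_image(px)
        glcm = cooccurrence_matrix(img, full_mask(px.shape), d=1, angle_deg=0)
        assert glcm.p[0, 255] == pytest.approx(0.5)
        con, eng, hmg, ent, detail = texture_features(img, full_mask(px.shape), d=1, angles=(0,))
        assert con == pytest.approx(65025.0)
        assert eng == pytest.approx(0.5)
        assert hmg == pytest.approx(1.0 / 65026.0, rel=1e-9)
        assert ent == pytest.approx(1.0)

    def test_matches_enumeration_oracle_random_images(self, rng):
        for _ in range(20):
            size = int(rng.integers(4, 13))
            px = rng.integers(0, 8, (size, size))
            m = rng.random((size, size)) < 0.8
            m[0, 0] = m[-1, -1] = True
            img = make_image(px)
            for d in (1, 2):
                if size <= d:
                    continue
                try:
                    exp = texture_by_enumeration(px.tolist(), m.tolist(), d)
                except ValueError:
                    continue
                con, eng, hmg, ent, _ = texture_features(img, PixelMask(mask=m), d=d)
                assert con == pytest.approx(exp["contrast"], rel=1e-9)
                assert eng == pytest.approx(exp["energy"], rel=1e-9)
                assert hmg == pytest.approx(exp["homogeneity"], rel=1e-9)
                assert ent == pytest.approx(exp["entropy"], rel=1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_feature_bounds(self, seed):
        r = np.random.default_rng(seed)
        px = r.integers(0, 256, (12, 12))
        img = make_image(px)
        con, eng, hmg, ent, _ = texture_features(img, full_mask((12, 12)), d=1)
        assert 0 <= con <= 255**2
        assert 0 < eng <= 1
        assert 0 < hmg <= 1
        assert ent >= 0


class TestExtractFeatures:
    def _long_setup(self, rng):
        px = rng.integers(20, 200, (40, 60))
        img = make_image(px, view="longitudinal")
        roi = band([[5, 8], [55, 8]], [[5, 30], [55, 30]])
        return img, roi

    def test_longitudinal_feature_set(self, rng):
        img, roi = self._long_setup(rng)
        fs = extract_features(img, roi, FeatureConfig(distance=2))
        assert set(fs.values) == set(LONGITUDINAL_FEATURES)
        assert "width" not in fs.values and "area" not in fs.values

    def test_transverse_feature_set(self, rng):
        px = rng.integers(20, 200, (40, 60))
        img = make_image(px, view="transverse")
        theta = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        verts = np.column_stack([30 + 20 * np.cos(theta), 20 + 12 * np.sin(theta)])
        roi = RegionOfInterest(kind="contour", view="transverse", contour=verts)
        fs = extract_features(img, roi, FeatureConfig(distance=2))
        assert set(fs.values) == set(TRANSVERSE_FEATURES)

    def test_view_mismatch_errors(self, rng):
        img, roi = self._long_setup(rng)
        img_t = make_image(img.pixels, view="transverse")
        with pytest.raises(ROIError, match="view"):
            extract_features(img_t, roi)

    def test_entropy_mode_selects_convention(self, rng):
        img, roi = self._long_setup(rng)
        hist = extract_features(img, roi, FeatureConfig(distance=2, entropy_mode="histogram"))
        co = extract_features(img, roi, FeatureConfig(distance=2, entropy_mode="cooccurrence"))
        assert hist["entropy"] == pytest.approx(hist.detail["entropy_histogram"])
        assert co["entropy"] == pytest.approx(co.detail["entropy_cooccurrence"])
        assert hist.detail["entropy_histogram"] <= 8.0 + 1e-12

    def test_constant_roi_flags_undefined(self):
        img = make_image(np.full((40, 60), 77), view="longitudinal")
        roi = band([[5, 8], [55, 8]], [[5, 30], [55, 30]])
        fs = extract_features(img, roi, FeatureConfig(distance=2))
        assert fs.undefined == {"skewness", "kurtosis"}
        assert fs["variance"] == 0.0
        assert fs["energy"] == pytest.approx(1.0)
        assert fs["homogeneity"] == pytest.approx(1.0)
        assert fs["contrast"] == 0.0
        assert fs["entropy"] == 0.0

    def test_geometric_ground_truth_within_2pct(self, cal_01mm):
        # rectangle band phantom: exact thickness 0.25 cm
        img = make_image(np.zeros((60, 80), int), view="longitudinal")
        roi = band([[10, 15], [70, 15]], [[10, 40], [70, 40]])
        fs = extract_features(img, roi, FeatureConfig(distance=2))
        assert fs["thickness"] == pytest.approx(0.25, rel=0.02)
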