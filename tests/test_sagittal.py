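"""Sagittal measurement chain: contours, KL, crop, rotation, KT, parenchyma."""

import numpy as np
import pytest
from scipy.ndimage import binary_erosion

from renalus.sagittal import (
    contour_pixels,
    extract_contour,
    kidney_length,
    kidney_thickness_sagittal,
    kl_axis_angle,
    parenchymal_thickness,
    rotate_to_horizontal,
    tailored_crop,
    upper_contour,
)
from renalus.axial import principal_axis_angle
from renalus.types import Measurement, Point

from tests.conftest import ellipse_mask, random_phantom_masks


class TestContour:
    def test_filled_square_has_ring_of_eight(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        pts = extract_contour(m)
        assert len(pts) == 8
        assert Point(2, 2) not in pts

    def test_single_pixel_is_its_own_contour(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        assert extract_contour(m) == [Point(1, 1)]

    def test_matches_erosion_difference_oracle_on_random_blobs(self, rng):
        for cap, _ in random_phantom_masks(5, 11):
            expected = cap & ~binary_erosion(
                cap, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
                border_value=0,
            )
            got = {(p.row, p.col) for p in extract_contour(cap)}
            assert got == set(map(tuple, np.argwhere(expected)))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            contour_pixels(np.zeros((4, 4), bool))


class TestKidneyLength:
    def test_three_four_five_triangle(self):
        m = np.zeros((8, 8), bool)
        m[0, 0] = m[3, 4] = True
        assert kidney_length(m, 1.0).length_px == pytest.approx(5.0)

    def test_ellipse_length_matches_axis(self):
        m = ellipse_mask((160, 300), (80, 150), 100, 40)
        kl = kidney_length(m, 0.3)
        assert kl.length_mm == pytest.approx(60.0, abs=0.3)

    def test_matches_bruteforce_over_all_contour_pairs(self):
        for cap, _ in random_phantom_masks(5, 21):
            pts = contour_pixels(cap).astype(float)
            d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            assert kidney_length(cap, 1.0).length_px ** 2 == pytest.approx(
                d2.max(), abs=1e-6
            )

    def test_single_pixel_degenerate_warning(self):
        m = np.zeros((4, 4), bool)
        m[2, 2] = True
        kl = kidney_length(m, 1.0)
        assert kl.length_px == 0.0 and kl.warnings


class TestTailoredCrop:
    def test_contains_both_endpoints(self):
        img = np.arange(200 * 200.0).reshape(200, 200)
        kl = Measurement("KL", Point(10, 10), Point(10, 110), 1.0)
        crop, (r0, c0) = tailored_crop(img, kl, margin=0.1)
        assert crop.shape[0] == crop.shape[1] >= 100
        for p in (kl.p1, kl.p2):
            assert 0 <= p.row - r0 < crop.shape[0]
            assert 0 <= p.col - c0 < crop.shape[1]

    def test_offset_roundtrip_recovers_values(self):
        img = np.arange(100 * 100.0).reshape(100, 100)
        kl = Measurement("KL", Point(30, 20), Point(60, 70), 1.0)
        crop, (r0, c0) = tailored_crop(img, kl, margin=0.2)
        r, c = int(kl.p1.row), int(kl.p1.col)
        assert crop[r - r0, c - c0] == img[r, c]

    def test_corner_endpoints_stay_square_with_padding(self):
        img = np.ones((50, 50))
        kl = Measurement("KL", Point(0, 0), Point(0, 40), 1.0)
        crop, (r0, c0) = tailored_crop(img, kl, margin=0.1)
        assert crop.shape[0] == crop.shape[1]
        assert r0 < 0  # padded above the image edge

    def test_zero_length_rejected(self):
        kl = Measurement("KL", Point(5, 5), Point(5, 5), 1.0)
        with pytest.raises(ValueError):
            tailored_crop(np.ones((10, 10)), kl)


class TestRotation:
    def test_identity_for_zero_angle(self):
        m = ellipse_mask((60, 80), (30, 40), 25, 10)
        rot, rec = rotate_to_horizontal(m, 0.0)
        r0 = (rot.shape[0] - m.shape[0]) // 2
        c0 = (rot.shape[1] - m.shape[1]) // 2
        assert np.array_equal(rot[r0 : r0 + 60, c0 : c0 + 80], m)

    def test_tilted_ellipse_becomes_horizontal(self):
        m = ellipse_mask((200, 200), (100, 100), 60, 25, angle_deg=30.0)
        rot, _ = rotate_to_horizontal(m, 30.0)
        assert abs(principal_axis_angle(rot).angle_deg) < 1.0

    def test_area_preserved_within_two_percent(self):
        m = ellipse_mask((200, 200), (100, 100), 60, 25, angle_deg=17.0)
        rot, _ = rotate_to_horizontal(m, 17.0)
        assert rot.sum() == pytest.approx(m.sum(), rel=0.02)

    def test_point_roundtrip_is_isometric(self, rng):
        m = ellipse_mask((100, 100), (50, 50), 30, 12, angle_deg=40.0)
        _, rec = rotate_to_horizontal(m, 40.0)
        pts = [Point(float(r), float(c)) for r, c in rng.uniform(10, 90, (5, 2))]
        back = rec.invert_points(rec.apply_points(pts))
        for p, q in zip(pts, back):
            assert p.distance_to(q) < 0.5
        d_orig = pts[0].distance_to(pts[1])
        fwd = rec.apply_points(pts[:2])
        assert fwd[0].distance_to(fwd[1]) == pytest.approx(d_orig, abs=0.5)


class TestThickness:
    def test_horizontal_ellipse_vertical_extent(self):
        m = ellipse_mask((120, 200), (60, 100), 50, 20)
        kt = kidney_thickness_sagittal(m, 1.0)
        assert kt.length_px == pytest.approx(40.0, abs=1.0)

    def test_rectangle_pixel_center_distance(self):
        m = np.zeros((20, 20), bool)
        m[5:12, 3:15] = True  # 7 rows tall
        assert kidney_thickness_sagittal(m, 1.0).length_px == 6.0

    def test_single_row_degenerate_warning(self):
        m = np.zeros((5, 9), bool)
        m[2, 1:8] = True
        kt = kidney_thickness_sagittal(m, 1.0)
        assert kt.length_px == 0.0 and kt.warnings


class TestParenchyma:
    def test_concentric_ellipses_thickness_at_pole(self):
        cap = ellipse_mask((120, 220), (60, 110), 50, 20)
        sin = ellipse_mask((120, 220), (60, 110), 25, 10)
        m = parenchymal_thickness(cap, sin, 1.0)
        assert m.length_px == pytest.approx(25.0, abs=1.0)

    def test_coincident_masks_give_zero(self):
        cap = ellipse_mask((60, 100), (30, 50), 30, 12)
        assert parenchymal_thickness(cap, cap, 1.0).length_px == 0.0

    def test_maxmin_never_exceeds_maxmax(self):
        for cap, sin in random_phantom_masks(5, 31):
            lo = parenchymal_thickness(cap, sin, 1.0, strategy="maxmin").length_px
            hi = parenchymal_thickness(cap, sin, 1.0, strategy="maxmax").length_px
            assert lo <= hi + 1e-9

    def test_empty_sinus_rejected(self):
        cap = ellipse_mask((60, 100), (30, 50), 30, 12)
        with pytest.raises(ValueError, match="sinus"):
            parenchymal_thickness(cap, np.zeros_like(cap), 1.0)


class TestInvariances:
    def test_translation_invariance_of_measurements(self):
        a = ellipse_mask((200, 300), (90, 140), 70, 30)
        b = np.roll(np.roll(a, 13, axis=0), -21, axis=1)
        assert kidney_length(a, 1.0).length_px == kidney_length(b, 1.0).length_px
        assert (
            kidney_thickness_sagittal(a, 1.0).length_px
            == kidney_thickness_sagittal(b, 1.0).length_px
        )

    def test_rotation_equivariance_of_kidney_length(self):
        a = ellipse_mask((300, 300), (150, 150), 70, 30, angle_deg=0.0)
        b = ellipse_mask((300, 300), (150, 150), 70, 30, angle_deg=28.0)
        la = kidney_length(a, 1.0).length_px
        lb = kidney_length(b, 1.0).length_px
        assert lb == pytest.approx(la, abs=1.5)

    def test_kl_axis_angle_recovers_tilt(self):
        m = ellipse_mask((300, 300), (150, 150), 80, 30, angle_deg=20.0)
        kl = kidney_length(m, 1.0)
        assert abs(kl_axis_angle(kl)) == pytest.approx(20.0, abs=1.5)

    def test_upper_contour_is_per_column_minimum(self):
        m = ellipse_mask((60, 100), (30, 50), 30, 12)
        up = upper_contour(m)
        rows, cols = np.nonzero(m)
        for r, c in up[::7]:
            assert r == rows[cols == c].min()
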