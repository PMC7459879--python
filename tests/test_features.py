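"""ABCD geometry and color classification."""

import math

import numpy as np
import pytest

from dermoseg.features import (
    CameraModel,
    Contour,
    assess_asymmetry,
    center_resultant,
    classify_colors,
    extract_contour,
    lesion_diameter,
    mask_centroid,
    physical_scale,
    polygon_area,
    probe_intersections,
    probe_line_slope,
    signed_area,
)
from dermoseg.phantoms import PhantomSpec, class_rgb, generate_phantom

from conftest import disk_mask


class TestContour:
    def test_filled_square_boundary(self):
        mask = np.zeros((7, 7), bool)
        mask[2:5, 2:5] = True
        c = extract_contour(mask)
        assert len(c) == 8
        assert {tuple(p) for p in c.points} == {
            (x, y) for x in (2, 3, 4) for y in (2, 3, 4) if not (x == 3 and y == 3)
        }

    def test_disk_contour_length_bounds(self):
        r = 20
        c = extract_contour(disk_mask(center=(48, 48), radius=r))
        closed = np.vstack([c.points, c.points[:1]])
        path = float(np.hypot(*np.diff(closed, axis=0).T).sum())
        assert 0.9 * 2 * math.pi * r <= path <= 1.5 * 2 * math.pi * r

    def test_consecutive_points_8_connected(self):
        c = extract_contour(disk_mask(radius=15))
        steps = np.abs(np.diff(np.vstack([c.points, c.points[:1]]), axis=0))
        assert steps.max() <= 1

    def test_two_blobs_traces_larger_with_warning(self):
        mask = np.zeros((40, 40), bool)
        mask[5:10, 5:10] = True  # 25 px
        mask[20:32, 20:32] = True  # 144 px
        with pytest.warns(UserWarning):
            c = extract_contour(mask)
        assert c.points[:, 0].min() >= 19

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_contour(np.zeros((10, 10), bool))


class TestResultantCenter:
    def test_two_points_is_midpoint(self):
        c = center_resultant(np.array([[0, 0], [4, 8]]))
        assert (c.x, c.y) == (2, 4)

    def test_repeated_point_is_fixed_point(self):
        c = center_resultant(np.tile([[3.5, -2.0]], (17, 1)))
        assert (c.x, c.y) == (3.5, -2.0)

    def test_three_point_closed_form(self):
        # x0 = (x1 + 2^0 x2 + 2^1 x3) / 2^2
        c = center_resultant(np.array([[0, 0], [4, 0], [8, 0]]))
        assert c.x == pytest.approx((0 + 4 + 2 * 8) / 4)

    def test_matches_power_weighted_closed_form(self, rng):
        """Iterated midpoints equal the 2^(i-2)/2^(n-1) weighted sum."""
        for n in range(1, 31):
            pts = rng.uniform(-100, 100, (n, 2))
            c = center_resultant(pts)
            if n == 1:
                expect = pts[0]
            else:
                w = np.concatenate([[1.0], 2.0 ** np.arange(0, n - 1)])
                expect = (w[:, None] * pts).sum(0) / 2.0 ** (n - 1)
            assert np.allclose([c.x, c.y], expect, atol=1e-9)


class TestProbes:
    def test_slope_examples(self):
        assert math.trunc(probe_line_slope(5.0) * 1e4) / 1e4 == 0.0874
        assert probe_line_slope(45.0) == pytest.approx(1.0)
        assert probe_line_slope(0.0) == 0.0
        with pytest.raises(ValueError):
            probe_line_slope(90.0)

    def test_circle_probe_radii_equal(self):
        mask = disk_mask(radius=25)
        c = extract_contour(mask)
        center = mask_centroid(mask)
        for angle in (0, 30, 90, 145):
            p = probe_intersections(c, center, angle)
            assert p.dk1 == pytest.approx(25, abs=1.5)
            assert p.dk2 == pytest.approx(25, abs=1.5)

    def test_square_horizontal_probe_half_width(self):
        mask = np.zeros((40, 40), bool)
        mask[10:31, 5:36] = True  # 31 x 21 rectangle
        c = extract_contour(mask)
        center = mask_centroid(mask)
        p = probe_intersections(c, center, 0.0)
        assert p.dk1 == pytest.approx(15, abs=1.0)
        assert p.dk2 == pytest.approx(15, abs=1.0)

    def test_vertical_probe_uses_x_equals_x0(self):
        mask = disk_mask(radius=18)
        c = extract_contour(mask)
        p = probe_intersections(c, mask_centroid(mask), 90.0)
        assert p.slope is None
        assert p.dk1 == pytest.approx(18, abs=1.5)


class TestAsymmetry:
    def test_disk_is_symmetric(self):
        mask = disk_mask(radius=28)
        asym, frac, probes = assess_asymmetry(
            extract_contour(mask), mask_centroid(mask)
        )
        assert not asym and frac <= 0.1
        assert len(probes) == 36

    def test_centered_ellipse_is_symmetric(self):
        yy, xx = np.mgrid[0:96, 0:128]
        mask = ((xx - 63.5) / 40) ** 2 + ((yy - 47.5) / 20) ** 2 <= 1
        asym, frac, _ = assess_asymmetry(extract_contour(mask), mask_centroid(mask))
        assert not asym

    def test_notched_disk_is_asymmetric(self):
        spec = PhantomSpec(seed=5, shape="notched-disk", notch_fraction=0.35,
                           radius=30, noise_sd=0)
        _, truth = generate_phantom(spec)
        asym, frac, _ = assess_asymmetry(truth.contour, mask_centroid(truth.mask))
        assert asym and frac > 0.5

    def test_invalid_angle_step_rejected(self):
        mask = disk_mask(radius=10)
        with pytest.raises(ValueError):
            assess_asymmetry(extract_contour(mask), mask_centroid(mask), angle_step=7)


class TestColors:
    def _uniform_lesion(self, label):
        img = np.full((64, 64, 3), 220, np.uint8)
        mask = disk_mask((64, 64), radius=20)
        img[mask] = class_rgb(label)
        return img, mask

    @pytest.mark.parametrize("label", [1, 2, 3, 4, 5, 6])
    def test_uniform_lesion_single_class(self, label):
        img, mask = self._uniform_lesion(label)
        _, colors = classify_colors(img, mask, smooth=None)
        assert colors == {label}

    def test_pixels_outside_boxes_unlabeled(self):
        img = np.full((32, 32, 3), 128, np.uint8)  # gray: S=0, V=50 -> no box
        mask = np.ones((32, 32), bool)
        mask[:2] = False
        cmap, colors = classify_colors(img, mask, smooth=None)
        assert colors == set()
        assert (cmap.labels == 0).all()

    def test_two_tone_lesion_two_classes(self):
        img = np.full((64, 64, 3), 220, np.uint8)
        mask = disk_mask((64, 64), radius=22)
        left = mask & (np.arange(64)[None, :] < 32)
        img[mask] = class_rgb(1)
        img[left] = class_rgb(5)
        _, colors = classify_colors(img, mask, smooth=None)
        assert colors == {1, 5}

    def test_background_never_affects_labels(self, rng):
        img, mask = self._uniform_lesion(2)
        cmap1, colors1 = classify_colors(img, mask)
        other = img.copy()
        other[~mask] = rng.integers(0, 256, (int((~mask).sum()), 3))
        cmap2, colors2 = classify_colors(other, mask)
        assert colors1 == colors2
        assert (cmap1.labels == cmap2.labels).all()

    def test_uniform_region_interior_suppressed_border_kept(self):
        img, mask = self._uniform_lesion(1)
        cmap, colors = classify_colors(img, mask, smooth=None, min_pixels=1)
        assert colors == {1}
        inner = disk_mask((64, 64), radius=17)
        assert not cmap.kept[inner].any()  # plus operation removes interior
        assert cmap.kept.sum() > 0


class TestDiameterArea:
    def test_square_corner_diameter(self):
        pts = np.array([[0, 0], [0, 10], [10, 10], [10, 0]], float)
        d, ends = lesion_diameter(pts)
        assert d == pytest.approx(math.sqrt(200))
        assert set(map(tuple, ends)) in ({(0.0, 0.0), (10.0, 10.0)},
                                         {(0.0, 10.0), (10.0, 0.0)})

    def test_disk_diameter_near_2r(self):
        c = extract_contour(disk_mask(radius=25))
        d, _ = lesion_diameter(c)
        assert abs(d - 50) <= 2

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(25):
            pts = rng.uniform(0, 100, (40, 2))
            d, _ = lesion_diameter(pts)
            best = max(
                math.dist(pts[i], pts[j])
                for i in range(len(pts))
                for j in range(i + 1, len(pts))
            )
            assert d == pytest.approx(best, abs=1e-9)

    def test_unit_square_and_triangle_area(self):
        assert polygon_area(np.array([[0, 0], [1, 0], [1, 1], [0, 1]])) == 1
        assert polygon_area(np.array([[0, 0], [4, 0], [0, 3]])) == 6

    def test_area_translation_invariant_and_sign_flips(self, rng):
        pts = rng.uniform(0, 50, (12, 2))
        hull_order = np.argsort(np.arctan2(*(pts - pts.mean(0)).T[::-1]))
        poly = pts[hull_order]
        a = signed_area(poly)
        assert signed_area(poly + [123.4, -56.7]) == pytest.approx(a)
        assert signed_area(poly[::-1]) == pytest.approx(-a)
        assert polygon_area(poly[::-1]) == pytest.approx(abs(a))

    def test_convex_polygon_matches_fan_triangulation(self, rng):
        from scipy.spatial import ConvexHull

        for _ in range(30):
            pts = rng.uniform(-50, 50, (int(rng.integers(6, 40)), 2))
            hull = ConvexHull(pts)
            poly = pts[hull.vertices]
            n = poly.shape[0]
            fan = sum(
                0.5
                * abs(
                    (poly[i][0] - poly[0][0]) * (poly[i + 1][1] - poly[0][1])
                    - (poly[i + 1][0] - poly[0][0]) * (poly[i][1] - poly[0][1])
                )
                for i in range(1, n - 1)
            )
            assert polygon_area(poly) == pytest.approx(fan, abs=1e-9)


class TestPhysicalScale:
    def test_known_camera_geometry(self):
        cam = CameraModel(f=3.5, u=80.0, pixel_pitch=0.005)
        length, area, units = physical_scale(100.0, 0.0, cam)
        assert units == "mm"
        assert length == pytest.approx(0.5 * (83.5 / 3.5))

    def test_missing_pitch_stays_in_units(self):
        cam = CameraModel(f=3.5, u=80.0)
        length, area, units = physical_scale(100.0, 400.0, cam)
        assert (length, area, units) == (100.0, 400.0, "units")

    def test_magnification_monotone_in_distance(self):
        lengths = [
            physical_scale(10.0, 0.0, CameraModel(f=3.5, u=u, pixel_pitch=0.01))[0]
            for u in (1.0, 10.0, 100.0)
        ]
        assert lengths == sorted(lengths)
        near = physical_scale(10.0, 0.0, CameraModel(f=3.5, u=1e-9, pixel_pitch=0.01))
        assert near[0] == pytest.approx(0.1, rel=1e-6)  # scale -> 1 at u -> 0

    def test_invalid_camera_rejected(self):
        with pytest.raises(ValueError):
            CameraModel(f=0.0, u=80.0)
        with pytest.raises(ValueError):
            CameraModel(f=3.5, u=-1.0)
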