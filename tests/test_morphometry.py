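"""Morphometric feature extraction: hand-counted cases, independent
oracles (rasterisation, two-pass variance, scikit-image regionprops,
analytic dome volume) and the invariant suite over random scenes."""

import numpy as np
import pytest
from skimage import measure as skmeasure

from broilerweight import (
    BirdSpec,
    DepthImage,
    SceneSpec,
    FEATURE_NAMES,
    approximate_volume,
    box_features,
    depth_statistics,
    extract_all_features,
    extract_contour,
    fit_ellipse,
    generate_depth_scene,
)
from broilerweight import geometry
from conftest import random_blob_mask


def filled_ellipse_mask(shape, center, a, b, angle=0.0):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dy, dx = rows - center[0], cols - center[1]
    c, s = np.cos(angle), np.sin(angle)
    u = (dx * c + dy * s) / a
    v = (-dx * s + dy * c) / b
    return u * u + v * v <= 1.0


class TestExtractContour:
    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_contour(np.zeros((5, 5), dtype=bool))

    def test_degenerate_single_pixel_rejected(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        with pytest.raises(ValueError, match="3 px"):
            extract_contour(mask)

    def test_thin_line_rejected(self):
        mask = np.zeros((5, 9), dtype=bool)
        mask[2, 1:8] = True
        with pytest.raises(ValueError):
            extract_contour(mask)

    def test_filled_square_reduces_to_four_corners(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[4:14, 3:13] = True
        contour = extract_contour(mask)
        assert len(contour.vertices) == 4
        assert contour.perimeter == pytest.approx(36.0)
        assert geometry.polygon_area(contour.vertices) == pytest.approx(81.0)
        assert geometry.polygon_signed_area(contour.vertices) > 0  # CCW

    def test_random_blob_area_close_to_pixel_count(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            mask = random_blob_mask(rng)
            contour = extract_contour(mask)
            area = geometry.polygon_area(contour.vertices)
            npx = int(mask.sum())
            # contour on pixel centres undershoots the count by ~perimeter/2
            assert abs(area - npx) <= contour.perimeter

    def test_largest_component_wins(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[2:6, 2:6] = True  # 16 px
        mask[10:25, 10:25] = True  # 225 px
        contour = extract_contour(mask)
        xs, ys = contour.vertices[:, 0], contour.vertices[:, 1]
        assert xs.min() >= 10 and ys.min() >= 10


class TestFitEllipse:
    def test_disc_is_round(self):
        mask = filled_ellipse_mask((80, 80), (40, 40), 30, 30)
        major, minor, ecc = fit_ellipse(mask)
        assert ecc < 0.02
        assert major == pytest.approx(minor, rel=0.02)
        assert major == pytest.approx(60.0, rel=0.05)  # diameter of the disc

    def test_axis_ratio_gives_expected_eccentricity(self):
        mask = filled_ellipse_mask((120, 120), (60, 60), 40, 20)
        _major, _minor, ecc = fit_ellipse(mask)
        assert ecc == pytest.approx(np.sqrt(1 - 0.25), abs=0.02)

    @pytest.mark.parametrize("angle", np.linspace(0, np.pi, 7))
    def test_axis_lengths_invariant_to_rotation(self, angle):
        mask = filled_ellipse_mask((140, 140), (70, 70), 45, 25, angle)
        major, minor, _ = fit_ellipse(mask)
        assert major == pytest.approx(90.0, rel=0.02)
        assert minor == pytest.approx(50.0, rel=0.02)

    def test_matches_regionprops(self):
        """Independent cross-check against scikit-image's moments route."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            mask = random_blob_mask(rng)
            major, minor, ecc = fit_ellipse(mask)
            props = skmeasure.regionprops(mask.astype(int))[0]
            assert major == pytest.approx(props.axis_major_length, rel=1e-9)
            assert minor == pytest.approx(props.axis_minor_length, rel=1e-9)
            assert ecc == pytest.approx(props.eccentricity, abs=1e-9)

    def test_too_small_mask_rejected(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1, 1] = mask[1, 2] = mask[2, 1] = True
        with pytest.raises(ValueError):
            fit_ellipse(mask)


class TestBoxFeatures:
    def test_rectangle_fills_its_box(self):
        rect = np.array([(0, 0), (8, 0), (8, 5), (0, 5)], dtype=float)
        box = box_features(rect)
        assert box["width"] == 8 and box["height"] == 5
        assert box["area_to_bbox_ratio"] == pytest.approx(1.0)

    def test_right_triangle_is_half_its_box(self):
        tri = np.array([(0, 0), (4, 0), (0, 3)], dtype=float)
        assert box_features(tri)["area_to_bbox_ratio"] == pytest.approx(0.5)

    def test_ratio_never_exceeds_one(self):
        rng = np.random.default_rng(29)
        for _ in range(30):
            mask = random_blob_mask(rng)
            contour = extract_contour(mask)
            assert box_features(contour)["area_to_bbox_ratio"] <= 1 + 1e-9

    def test_min_area_rect_no_larger_than_bbox(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            mask = random_blob_mask(rng)
            box = box_features(extract_contour(mask))
            assert (
                box["min_rect_long"] * box["min_rect_short"]
                <= box["width"] * box["height"] + 1e-6
            )


class TestDepthStatistics:
    def _img(self, values, H=1000.0):
        return DepthImage(values=np.asarray(values, dtype=float), ground_distance=H)

    def test_constant_field(self):
        img = self._img(np.full((4, 4), 900.0))
        stats = depth_statistics(img, np.ones((4, 4), dtype=bool))
        assert stats["depth_max"] == stats["depth_min"] == stats["depth_mean"] == 900
        assert stats["depth_range"] == stats["depth_sd"] == 0
        assert stats["dist_min_to_avg"] == stats["dist_max_to_avg"] == 0

    def test_hand_arithmetic(self):
        img = self._img([[8, 9], [10, 13]])
        stats = depth_statistics(img, np.ones((2, 2), dtype=bool))
        assert stats["depth_mean"] == pytest.approx(10.0)
        assert stats["depth_range"] == pytest.approx(5.0)
        assert stats["depth_sum"] == pytest.approx(40.0)
        assert stats["depth_sd"] == pytest.approx(np.sqrt(3.5))

    def test_sd_matches_two_pass_oracle(self):
        rng = np.random.default_rng(37)
        values = rng.uniform(500, 1000, size=(64, 64))
        mask = random_blob_mask(rng)
        stats = depth_statistics(self._img(values), mask)
        d = values[mask]
        mu = d.sum() / d.size
        two_pass_sd = np.sqrt(((d - mu) ** 2).sum() / d.size)
        assert stats["depth_sd"] == pytest.approx(two_pass_sd, abs=1e-9)

    def test_missing_pixels_excluded(self):
        values = np.full((4, 4), 900.0)
        values[0, 0] = 0.0
        stats = depth_statistics(self._img(values), np.ones((4, 4), dtype=bool))
        assert stats["depth_sum"] == pytest.approx(900.0 * 15)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            depth_statistics(self._img(np.zeros((3, 3))), np.ones((3, 3), dtype=bool))


class TestApproximateVolume:
    def test_flat_object_has_zero_volume(self):
        img = DepthImage(values=np.full((6, 6), 10.0), ground_distance=10.0)
        mask = np.zeros((6, 6), dtype=bool)
        mask[1:5, 1:5] = True
        contour = extract_contour(mask)
        assert approximate_volume(16.0, img, mask, contour) == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        img = DepthImage(values=np.array([[8.0, 8.0], [9.0, 10.0]]),
                         ground_distance=10.0)
        mask = np.ones((2, 2), dtype=bool)
        contour = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], dtype=float)
        assert approximate_volume(4.0, img, mask, contour) == pytest.approx(5.0)

    def test_dome_volume_within_3pct_of_analytic(self, canonical_dome):
        _spec, img, masks, truths = canonical_dome
        feats = extract_all_features(img, masks[0])
        assert feats.f17_approx_volume == pytest.approx(
            truths[0].analytic_volume, rel=0.03
        )


class TestExtractAllFeatures:
    def test_all_25_names_populated(self, canonical_dome):
        _spec, img, masks, _ = canonical_dome
        feats = extract_all_features(img, masks[0])
        d = feats.to_dict()
        assert list(d) == list(FEATURE_NAMES)
        assert len(d) == 25
        assert np.all(np.isfinite(feats.to_array()))

    def test_translation_invariance(self):
        kw = dict(shape=(120, 120), ground_distance=1000.0, depth_noise_sigma=0.0,
                  missing_pixel_rate=0.0, seed=4)
        bird = dict(a=25.0, b=17.0, h=80.0, orientation=0.9)
        s1 = SceneSpec(birds=(BirdSpec(center=(50.0, 48.0), **bird),), **kw)
        s2 = SceneSpec(birds=(BirdSpec(center=(55.0, 55.0), **bird),), **kw)
        img1, m1, _ = generate_depth_scene(s1)
        img2, m2, _ = generate_depth_scene(s2)
        f1 = extract_all_features(img1, m1[0]).to_array()
        f2 = extract_all_features(img2, m2[0]).to_array()
        assert np.allclose(f1, f2)

    def test_scaling_laws(self):
        kw = dict(shape=(200, 200), ground_distance=1000.0, depth_noise_sigma=0.0,
                  missing_pixel_rate=0.0, seed=4)
        small = SceneSpec(birds=(BirdSpec(center=(100.0, 100.0), a=30, b=30, h=80),), **kw)
        big = SceneSpec(birds=(BirdSpec(center=(100.0, 100.0), a=60, b=60, h=80),), **kw)
        f_small = extract_all_features(*_scene_first(small))
        f_big = extract_all_features(*_scene_first(big))
        assert f_big.f01_projected_area == pytest.approx(
            4 * f_small.f01_projected_area, rel=0.02
        )
        assert f_big.f02_contour_perimeter == pytest.approx(
            2 * f_small.f02_contour_perimeter, rel=0.02
        )

    def test_greens_area_flag_changes_volume_only(self, canonical_dome):
        _spec, img, masks, _ = canonical_dome
        f_px = extract_all_features(img, masks[0], volume_area="pixel_count")
        f_gr = extract_all_features(img, masks[0], volume_area="greens")
        a, b = f_px.to_array(), f_gr.to_array()
        differs = a != b
        assert differs.sum() == 1
        assert FEATURE_NAMES[int(np.argmax(differs))] == "f17_approx_volume"


def _scene_first(spec):
    img, masks, _ = generate_depth_scene(spec)
    return img, masks[0]


@pytest.fixture(scope="module")
def random_features():
    from broilerweight import random_scene_spec

    rng = np.random.default_rng(99)
    out = []
    for i in range(200):
        spec = random_scene_spec(rng, seed=1000 + i)
        img, masks, _ = generate_depth_scene(spec)
        out.append(extract_all_features(img, masks[0]))
    return out


class TestInvariantSuite:
    """Type invariants of the 25-feature vector over random scenes."""

    def test_area_and_perimeter_orderings(self, random_features):
        for f in random_features:
            assert f.f01_projected_area <= f.f05_hull_area + 1e-9
            assert f.f02_contour_perimeter >= f.f09_hull_perimeter - 1e-9
            assert f.f11_approx_contour_perimeter <= f.f02_contour_perimeter + 1e-9

    def test_ratios_in_unit_interval(self, random_features):
        for f in random_features:
            assert 0 < f.f12_area_to_bbox_ratio <= 1 + 1e-9
            assert 0 < f.f13_area_to_hull_ratio <= 1 + 1e-9
            assert 0 <= f.f08_eccentricity < 1

    def test_depth_identities(self, random_features):
        for f in random_features:
            assert f.f21_depth_range == pytest.approx(
                f.f18_depth_max - f.f19_depth_min
            )
            assert f.f24_dist_min_to_avg_depth == pytest.approx(
                f.f20_depth_mean - f.f19_depth_min
            )
            assert f.f25_dist_max_to_avg_depth == pytest.approx(
                f.f18_depth_max - f.f20_depth_mean
            )

    def test_equivalent_diameter_identity(self, random_features):
        for f in random_features:
            circle_area = np.pi * (f.f16_equiv_diameter / 2) ** 2
            assert circle_area == pytest.approx(f.f01_projected_area, abs=1e-9)

    def test_defect_sum_bounds_max(self, random_features):
        for f in random_features:
            assert f.f15_defect_sum >= f.f14_defect_max >= 0
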