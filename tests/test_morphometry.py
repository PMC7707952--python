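"""Geometric and densitometric feature extraction against closed forms and
independent oracles (rasterization counts, brute-force distances, dense
resampling, per-pixel recomputation)."""

import math

import numpy as np
import pytest
import shapely

from cytodx.morphometry import (DegeneratePolygonError, ImagePatch,
                                MorphometryError, NucleusBoundary,
                                background_correct, caliper_diameters,
                                densitometric_features, ellipse_axes,
                                extract_features, fractal_dimension,
                                optical_density_map, polygon_area,
                                polygon_perimeter, radial_stats, roundness)
from cytodx.synthetic import render_nucleus

from conftest import koch_snowflake, random_convex_polygon, regular_polygon


# ---------------------------------------------------------------- polygons

class TestPolygonBasics:
    def test_unit_square_area_and_orientation(self, unit_square):
        assert polygon_area(unit_square) == pytest.approx(1.0)
        reversed_square = NucleusBoundary(unit_square.vertices[::-1])
        assert polygon_area(reversed_square) == pytest.approx(1.0)

    def test_area_matches_supersampled_raster_count(self, rng):
        poly = random_convex_polygon(rng, n_points=12)
        # pixel-count oracle at 100x supersampling
        v = poly.vertices
        xs = np.arange(math.floor(v[:, 0].min() * 100),
                       math.ceil(v[:, 0].max() * 100) + 1) + 0.5
        ys = np.arange(math.floor(v[:, 1].min() * 100),
                       math.ceil(v[:, 1].max() * 100) + 1) + 0.5
        gx, gy = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(shapely.Polygon(v * 100),
                                     gx.ravel(), gy.ravel())
        raster_area = inside.sum() / 100 ** 2
        assert polygon_area(poly) == pytest.approx(raster_area, rel=5e-3)

    def test_perimeter_closed_forms_and_oracle(self, unit_square, rng):
        assert polygon_perimeter(unit_square) == pytest.approx(4.0)
        circle = regular_polygon(256, 1.0)
        assert polygon_perimeter(circle) == pytest.approx(2 * math.pi, rel=1e-3)
        poly = random_convex_polygon(rng)
        v = np.vstack([poly.vertices, poly.vertices[:1]])
        edge_sum = sum(math.dist(v[i], v[i + 1]) for i in range(len(v) - 1))
        assert polygon_perimeter(poly) == pytest.approx(edge_sum, rel=1e-12)

    def test_degenerate_polygons_rejected(self):
        with pytest.raises(DegeneratePolygonError):
            NucleusBoundary(np.array([[0, 0], [1, 1]], float))
        with pytest.raises(DegeneratePolygonError):
            NucleusBoundary(np.array([[0, 0], [1, 1], [2, 2]], float))

    def test_geometric_invariances(self, rng):
        poly = random_convex_polygon(rng)
        a0 = polygon_area(poly)
        cal0 = caliper_diameters(poly)
        shifted = NucleusBoundary(poly.vertices + [123.4, -56.7])
        cycled = NucleusBoundary(np.roll(poly.vertices, 3, axis=0))
        assert polygon_area(shifted) == pytest.approx(a0, rel=1e-9)
        assert polygon_area(cycled) == pytest.approx(a0, rel=1e-9)
        s = 3.7
        scaled = NucleusBoundary(poly.vertices * s)
        assert polygon_area(scaled) == pytest.approx(a0 * s ** 2, rel=1e-9)
        assert caliper_diameters(scaled) == pytest.approx(
            tuple(c * s for c in cal0), rel=1e-9)


class TestCalipers:
    def test_square_two_angles(self, unit_square):
        # grid projections at 0° and 90° are both 1.0; the max is still the
        # exact pairwise bound (the diagonal), which the coarse grid misses
        assert caliper_diameters(unit_square, n_angles=2) == \
            pytest.approx((math.sqrt(2), 1.0, 1.0))

    def test_rectangle_extremes(self, rect_4x2):
        cmax, cmin, _ = caliper_diameters(rect_4x2, n_angles=180)
        assert cmax == pytest.approx(math.sqrt(20), rel=1e-3)
        assert cmin == pytest.approx(2.0, rel=1e-3)

    def test_max_equals_brute_force_pairwise_distance(self, rng):
        for _ in range(25):
            poly = random_convex_polygon(rng, n_points=10)
            cmax = caliper_diameters(poly)[0]
            v = poly.vertices
            d = np.sqrt(((v[:, None] - v[None]) ** 2).sum(-1)).max()
            assert cmax == pytest.approx(d, rel=1e-12)


class TestRadialStats:
    def test_circle(self):
        circ = regular_polygon(256, 10.0)
        rs = radial_stats(circ)
        assert rs.max_radius == pytest.approx(10.0, rel=5e-3)
        assert rs.min_radius == pytest.approx(10.0, rel=5e-3)
        assert rs.radius_ratio == pytest.approx(1.0, rel=5e-3)
        assert rs.centroid_inside

    def test_rectangle(self, rect_4x2):
        rs = radial_stats(rect_4x2)
        assert rs.max_radius == pytest.approx(math.sqrt(5), rel=0.02)
        assert rs.min_radius == pytest.approx(1.0, rel=0.02)

    def test_star_matches_dense_resampling_oracle(self, rng):
        t = np.linspace(0, 2 * math.pi, 40, endpoint=False)
        r = 10 + 4 * np.cos(5 * t)
        star = NucleusBoundary(np.column_stack([r * np.cos(t), r * np.sin(t)]))
        rs = radial_stats(star)
        # 10,000-point oracle
        from cytodx.morphometry import _resample_closed
        pts = _resample_closed(star.vertices, 10_000)
        c = star.polygon().centroid
        d = np.hypot(pts[:, 0] - c.x, pts[:, 1] - c.y)
        assert rs.max_radius == pytest.approx(d.max(), rel=0.01)
        assert rs.min_radius == pytest.approx(d.min(), rel=0.01)


class TestEllipseAxes:
    def test_ellipse_polygon_recovers_axes(self):
        t = np.linspace(0, 2 * math.pi, 256, endpoint=False)
        ell = NucleusBoundary(np.column_stack([20 * np.cos(t), 10 * np.sin(t)]))
        major, minor, ratio = ellipse_axes(ell)
        assert major == pytest.approx(40.0, rel=0.01)
        assert minor == pytest.approx(20.0, rel=0.01)
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_square_is_isotropic(self, unit_square):
        assert ellipse_axes(unit_square)[2] == pytest.approx(1.0, rel=1e-9)

    def test_moments_match_raster_oracle(self, rng):
        poly = random_convex_polygon(rng, n_points=12)
        v = poly.vertices * 20  # upscale for raster resolution
        big = NucleusBoundary(v)
        xs = np.arange(math.floor(v[:, 0].min()), math.ceil(v[:, 0].max()) + 1) + 0.5
        ys = np.arange(math.floor(v[:, 1].min()), math.ceil(v[:, 1].max()) + 1) + 0.5
        gx, gy = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(shapely.Polygon(v), gx.ravel(), gy.ravel())
        px, py = gx.ravel()[inside], gy.ravel()[inside]
        cov = np.cov(np.vstack([px, py]), ddof=0)
        lam = np.linalg.eigvalsh(cov)
        major, minor, _ = ellipse_axes(big)
        assert major == pytest.approx(4 * math.sqrt(lam[1]), rel=0.01)
        assert minor == pytest.approx(4 * math.sqrt(lam[0]), rel=0.01)


class TestRoundnessAndFractal:
    def test_roundness_closed_forms(self):
        assert roundness(math.pi, 2 * math.pi) == pytest.approx(1.0)
        assert roundness(1.0, 4.0) == pytest.approx(math.pi / 4)
        assert roundness(8.0, 12.0) == pytest.approx(4 * math.pi * 8 / 144)
        with pytest.raises(MorphometryError):
            roundness(0.0, 1.0)

    def test_roundness_never_exceeds_one(self, rng):
        for _ in range(50):
            poly = random_convex_polygon(rng)
            assert roundness(polygon_area(poly), polygon_perimeter(poly)) \
                <= 1 + 1e-9

    def test_smooth_curves_have_dimension_one(self):
        thin = NucleusBoundary(
            np.array([[0, 0], [60, 0], [60, 0.2], [0, 0.2]], float))
        assert fractal_dimension(thin) == pytest.approx(1.0, abs=0.1)
        assert fractal_dimension(regular_polygon(256, 30.0)) == \
            pytest.approx(1.0, abs=0.1)

    def test_koch_snowflake_dimension(self):
        fd = fractal_dimension(koch_snowflake(depth=4))
        assert fd == pytest.approx(math.log(4) / math.log(3), abs=0.1)


# ------------------------------------------------------------ densitometry

class TestBackgroundCorrection:
    def test_uniform_blank_is_identity(self, rng):
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        blank = np.full((32, 32, 3), 200, np.uint8)
        out = background_correct(ImagePatch(img, blank))
        np.testing.assert_array_equal(out.pixels, img)

    def test_gradient_blank_flattens_uniform_specimen(self):
        grad = np.tile(np.linspace(100, 200, 64)[None, :, None], (48, 1, 3))
        # specimen attenuates the illumination by a constant factor
        img = np.clip(np.rint(grad * 0.6), 0, 255).astype(np.uint8)
        out = background_correct(ImagePatch(img, grad.astype(np.uint8)))
        flat = out.pixels.astype(float)
        assert flat.max() - flat.min() <= 2.0  # uniform within rounding

    def test_matches_per_pixel_recomputation(self, rng):
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        blank = rng.integers(50, 256, (16, 16, 3), dtype=np.uint8)
        out = background_correct(ImagePatch(img, blank))
        bf = blank.astype(float)
        expected = np.clip(np.rint(
            img * bf.mean(axis=(0, 1)) / bf), 0, 255).astype(np.uint8)
        np.testing.assert_array_equal(out.pixels, expected)

    def test_missing_blank_is_identity(self, rng):
        img = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        out = background_correct(ImagePatch(img))
        np.testing.assert_array_equal(out.pixels, img)


class TestOpticalDensity:
    def test_white_pixels_have_zero_od(self, unit_square):
        img = np.full((4, 4, 3), 255, np.uint8)
        sq = NucleusBoundary(np.array([[0, 0], [3, 0], [3, 3], [0, 3]], float))
        od, mask = optical_density_map(ImagePatch(img), sq)
        assert od[mask].max() == 0.0

    def test_uniform_gray_closed_form(self):
        img = np.full((10, 10, 3), 127, np.uint8)
        sq = NucleusBoundary(np.array([[1, 1], [8, 1], [8, 8], [1, 8]], float))
        od, mask = optical_density_map(ImagePatch(img), sq)
        assert od[mask] == pytest.approx(math.log10(2), rel=1e-9)

    def test_matches_per_pixel_recomputation(self, rng):
        img = rng.integers(0, 256, (20, 20, 3), dtype=np.uint8)
        sq = NucleusBoundary(np.array([[2, 2], [17, 2], [17, 17], [2, 17]], float))
        od, mask = optical_density_map(ImagePatch(img), sq)
        lum = img.astype(float) @ np.array([0.299, 0.587, 0.114])
        expected = np.clip(-np.log10((lum + 1) / 256.0), 0, None)
        np.testing.assert_allclose(od[mask], expected[mask])

    def test_boundary_outside_image_rejected(self):
        img = np.full((10, 10, 3), 127, np.uint8)
        out = NucleusBoundary(np.array([[2, 2], [15, 2], [15, 8], [2, 8]], float))
        with pytest.raises(MorphometryError):
            optical_density_map(ImagePatch(img), out)


class TestDensitometricFeatures:
    def test_uniform_disc_has_zero_heterogeneity(self):
        patch, boundary, _ = render_nucleus(20, 20, od_level=0.3, size=(96, 96))
        d = densitometric_features(patch, boundary)
        assert d.sd_od == 0.0
        assert d.heterogeneity == 0.0

    def test_uniform_disc_margination_annulus_fraction(self):
        patch, boundary, _ = render_nucleus(20, 20, od_level=0.3, size=(96, 96))
        d = densitometric_features(patch, boundary)
        assert d.margination == pytest.approx(1 - (18 / 20) ** 2, abs=0.03)

    def test_two_tone_heterogeneity_matches_pixel_count(self):
        patch, boundary, _ = render_nucleus(
            20, 20, texture="two_tone", od_levels=(0.1, 0.5), size=(96, 96))
        d = densitometric_features(patch, boundary)
        od, mask = optical_density_map(patch, boundary)
        vals = od[mask]
        expected = (np.abs(vals - vals.mean()) > vals.std()).mean()
        assert d.heterogeneity == pytest.approx(expected)


class TestExtractFeatures:
    def test_rendered_ellipse_ground_truth(self):
        patch, boundary, truth = render_nucleus(
            20, 10, rotation=0.4, od_level=0.3, size=(96, 96))
        fv = extract_features(patch, boundary)
        assert fv.area == pytest.approx(truth["area"], rel=0.02)
        assert fv.aspect_ratio == pytest.approx(2.0, rel=0.02)
        assert fv.heterogeneity == 0.0

    def test_rendered_circle_is_round(self):
        patch, boundary, _ = render_nucleus(15, 15, od_level=0.3, size=(80, 80))
        fv = extract_features(patch, boundary)
        assert fv.roundness >= 0.95
        assert fv.radius_ratio <= 1.05

    def test_deterministic_and_ordered(self):
        patch, boundary, _ = render_nucleus(
            18, 11, rotation=1.0, texture="noise", od_level=0.3, size=(96, 96))
        fv1 = extract_features(patch, boundary)
        fv2 = extract_features(patch, boundary)
        assert fv1 == fv2
        assert fv1.min_caliper <= fv1.mean_caliper <= fv1.max_caliper
        assert fv1.min_od <= fv1.mean_od <= fv1.max_od
        assert fv1.min_radius <= fv1.max_radius

    def test_errors_name_the_feature(self):
        patch, boundary, _ = render_nucleus(10, 10, size=(64, 64))
        tiny = NucleusBoundary(boundary.vertices * 0.001 + 200)
        img = ImagePatch(np.full((64, 64, 3), 255, np.uint8))
        with pytest.raises(MorphometryError):
            extract_features(img, tiny)
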