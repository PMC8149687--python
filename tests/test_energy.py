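"""Data-attachment and regularization terms against independent oracles."""

import numpy as np
import pytest

from beastrack.contour import PolarContour, contour_mask, contour_polygon, make_ellipse_contour
from beastrack.energy import (
    EnergyConfig,
    area_gradient,
    area_stability,
    curvature_gradient,
    local_band,
    localized_means,
    overlap_penalty,
    proximity_penalty,
    total_regularization,
    yezzi_force,
)
from beastrack.energy import yezzi_forces


class TestEnergyConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            EnergyConfig(rho=0.5)
        with pytest.raises(ValueError):
            EnergyConfig(w_kappa=-1)
        with pytest.raises(ValueError):
            EnergyConfig(area_min=100, area_max=50)


class TestLocalBand:
    def test_band_along_radial_ray_of_circle(self, disk_image):
        c = make_ellipse_contour((48, 48), (16, 16), 0, 32)
        inside, outside = local_band(disk_image.shape, c, 0, 5)
        # node 0 is at angle 0: the normal is the +x axis through (64, 48)
        assert (inside[:, 1] == 48).all() and (outside[:, 1] == 48).all()
        assert (inside[:, 0] < 64).all() and (outside[:, 0] > 64).all()

    def test_band_sizes(self, disk_image):
        c = make_ellipse_contour((48, 48), (16, 16), 0, 32)
        for k in range(32):
            inside, outside = local_band(disk_image.shape, c, k, 5)
            assert len(inside) <= 5 and len(outside) <= 5

    def test_disk_membership_exhaustive(self, disk_image):
        c = make_ellipse_contour((48, 48), (20, 20), 0, 32)
        disk = disk_image > 0.5
        for k in range(32):
            inside, outside = local_band(disk_image.shape, c, k, 5)
            assert all(disk[y, x] for x, y in inside)
            assert not any(disk[y, x] for x, y in outside)


class TestLocalizedMeans:
    def test_step_image(self, disk_image):
        c = make_ellipse_contour((48, 48), (20, 20), 0, 32)
        u_in, u_out = localized_means(disk_image, c, 0, 5)
        assert u_in == pytest.approx(1.0)
        assert u_out == pytest.approx(0.1)

    def test_uniform_image(self):
        img = np.full((96, 96), 0.7)
        c = make_ellipse_contour((48, 48), (15, 15), 0, 32)
        u_in, u_out = localized_means(img, c, 3, 6)
        assert u_in == pytest.approx(0.7) and u_out == pytest.approx(0.7)

    def test_matches_exhaustive_pixel_classification(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 1, (96, 96))
        c = make_ellipse_contour((48, 48), (14, 11), 0.4, 32)
        for k in (0, 5, 17, 31):
            inside, outside = local_band(img.shape, c, k, 7)
            want = (
                float(np.mean([img[y, x] for x, y in inside])),
                float(np.mean([img[y, x] for x, y in outside])),
            )
            assert localized_means(img, c, k, 7) == pytest.approx(want)


def band_energy(image, contour, rho):
    """Mean-separation criterion summed over nodes: sum -(u_in - u_out)^2."""
    total = 0.0
    for k in range(contour.n_nodes):
        u_in, u_out = localized_means(image, contour, k, rho)
        total -= (u_in - u_out) ** 2
    return total


class TestYezziForce:
    def test_uniform_image_zero_force(self):
        img = np.full((96, 96), 0.4)
        c = make_ellipse_contour((48, 48), (15, 15), 0, 32)
        assert np.allclose(yezzi_forces(img, c, 5), 0.0)

    def test_contour_inside_disk_pushed_outward(self, disk_image):
        c = make_ellipse_contour((48, 48), (16, 16), 0, 32)
        assert (yezzi_forces(disk_image, c, 5) > 0).all()
        # oracle: the separation energy decreases with expansion
        grown = make_ellipse_contour((48, 48), (17, 17), 0, 32)
        assert band_energy(disk_image, grown, 5) < band_energy(disk_image, c, 5)

    def test_contour_outside_disk_pushed_inward(self, disk_image):
        c = make_ellipse_contour((48, 48), (24, 24), 0, 32)
        assert (yezzi_forces(disk_image, c, 5) < 0).all()
        shrunk = make_ellipse_contour((48, 48), (23, 23), 0, 32)
        assert band_energy(disk_image, shrunk, 5) < band_energy(disk_image, c, 5)

    def test_single_node_accessor(self, disk_image):
        c = make_ellipse_contour((48, 48), (16, 16), 0, 32)
        assert yezzi_force(disk_image, c, 0, 5) == yezzi_forces(disk_image, c, 5)[0]


class TestCurvatureGradient:
    def test_circle_all_zero(self):
        c = make_ellipse_contour((0, 0), (10, 10), 0, 32)
        assert np.allclose(curvature_gradient(c), 0.0)

    def test_concave_dent_support(self):
        radii = np.full(32, 12.0)
        radii[7:10] = 7.0  # dent produces concave shoulders
        c = PolarContour((0, 0), radii, 2)
        from beastrack.contour import local_mean_curvature

        k = local_mean_curvature(c)
        g = curvature_gradient(c)
        assert np.allclose(g[k >= 0], 0.0)
        assert (g[k < 0] < 0).all() and (k < 0).any()


class TestAreaTerms:
    @pytest.mark.parametrize(
        "area,expected", [(200, 0.0), (50, -50.0), (500, -100.0)]
    )
    def test_area_gradient_formula(self, area, expected):
        assert area_gradient(area, 100, 400) == expected

    @pytest.mark.parametrize(
        "a_t,a_prev,expected", [(100, 100, 0.0), (110, 100, 0.1), (90, 100, 0.1)]
    )
    def test_area_stability(self, a_t, a_prev, expected):
        assert area_stability(a_t, a_prev) == pytest.approx(expected)

    def test_first_frame_inactive(self):
        assert area_stability(123.0, None) == 0.0


class TestProximityPenalty:
    def test_distant_contours_zero(self):
        a = make_ellipse_contour((30, 50), (10, 10), 0, 32)
        b = make_ellipse_contour((80, 50), (10, 10), 0, 32)  # gap 30 px
        assert np.allclose(proximity_penalty(a, b, 5.0), 0.0)

    def test_penalty_is_threshold_minus_distance(self):
        a = make_ellipse_contour((30, 50), (10, 10), 0, 32)
        b = make_ellipse_contour((52, 50), (10, 10), 0, 32)  # nearest gap 2 px
        pen = proximity_penalty(a, b, 5.0)
        assert pen.max() == pytest.approx(3.0, abs=0.1)

    def test_distances_match_brute_force(self):
        rng = np.random.default_rng(7)
        a = PolarContour((40, 50), 10 + rng.uniform(-2, 2, 32), 2)
        b = PolarContour((62, 48), 9 + rng.uniform(-2, 2, 32), 2)
        dense = contour_polygon(b, 32)
        pen = proximity_penalty(a, b, 8.0)
        for k, p in enumerate(a.node_positions()):
            d = np.hypot(dense[:, 0] - p[0], dense[:, 1] - p[1]).min()
            inside = contour_mask(b, (96, 96))[
                min(95, int(round(p[1]))), min(95, int(round(p[0])))
            ]
            signed = -d if inside else d
            expected = max(8.0 - signed, 0.0)
            assert pen[k] == pytest.approx(expected, abs=0.5)

    def test_translation_invariance(self):
        a = make_ellipse_contour((40, 50), (10, 10), 0, 32)
        b = make_ellipse_contour((58, 50), (10, 10), 0, 32)
        p1 = proximity_penalty(a, b, 6.0)
        a2 = make_ellipse_contour((140, 150), (10, 10), 0, 32)
        b2 = make_ellipse_contour((158, 150), (10, 10), 0, 32)
        p2 = proximity_penalty(a2, b2, 6.0)
        assert np.allclose(p1, p2, atol=1e-6)


class TestOverlapPenalty:
    def test_disjoint_zero(self):
        a = make_ellipse_contour((30, 50), (10, 10), 0, 32)
        b = make_ellipse_contour((70, 50), (10, 10), 0, 32)
        e, fa, fb = overlap_penalty(a, b, 2.0)
        assert e == 0.0 and np.allclose(fa, 0) and np.allclose(fb, 0)

    def test_identical_circles_full_area(self):
        a = make_ellipse_contour((50, 50), (10, 10), 0, 32)
        b = make_ellipse_contour((50, 50), (10, 10), 0, 32)
        e, _, _ = overlap_penalty(a, b, 2.0)
        assert e == pytest.approx(2.0 * np.pi * 100, rel=0.01)

    def test_lens_area_matches_closed_form(self):
        # circles r=10 with centers 10 px apart: lens area = 2r^2 cos^-1(d/2r)
        # - d/2 sqrt(4r^2 - d^2)
        a = make_ellipse_contour((45, 50), (10, 10), 0, 64)
        b = make_ellipse_contour((55, 50), (10, 10), 0, 64)
        e, fa, fb = overlap_penalty(a, b, 1.0)
        lens = 2 * 100 * np.arccos(0.5) - 5 * np.sqrt(400 - 100)
        assert e == pytest.approx(lens, rel=0.02)
        # pixel-counting oracle; the thin lens loses a few boundary pixels to
        # center-in-polygon rasterization, hence the slightly wider band
        raster = (contour_mask(a, (100, 100)) & contour_mask(b, (100, 100))).sum()
        assert e == pytest.approx(raster, rel=0.04)
        # inward forces only on penetrating nodes
        assert (fa <= 0).all() and (fb <= 0).all() and fa.min() < 0

    def test_energy_symmetry(self):
        a = make_ellipse_contour((45, 50), (11, 9), 0.3, 32)
        b = make_ellipse_contour((56, 52), (10, 10), 0, 32)
        e_ab, _, _ = overlap_penalty(a, b, 1.5)
        e_ba, _, _ = overlap_penalty(b, a, 1.5)
        assert e_ab == pytest.approx(e_ba, rel=1e-6)


class TestTotalRegularization:
    def test_zero_weights_no_neighbors(self):
        cfg = EnergyConfig(w_kappa=0, w_area=0, w_area_stab=0, w_comp=0)
        c = make_ellipse_contour((50, 50), (10, 10), 0, 32)
        nf = total_regularization(c, [], None, cfg)
        assert np.allclose(nf.total(), 0.0)

    def test_isolated_circle_in_bounds_zero_force(self):
        cfg = EnergyConfig(area_min=100, area_max=500)
        c = make_ellipse_contour((50, 50), (10, 10), 0, 32)
        nf = total_regularization(c, [], None, cfg)
        assert np.allclose(nf.total(), 0.0, atol=1e-9)

    def test_termwise_additivity(self):
        cfg = EnergyConfig(area_min=200, area_max=280, w_comp=1.5, d_thresh=4.0)
        rng = np.random.default_rng(8)
        c = PolarContour((50, 50), 10 + rng.uniform(-2, 2, 32), 2)
        nb = make_ellipse_contour((66, 50), (9, 9), 0, 32)
        nf = total_regularization(c, [nb], 300.0, cfg)
        total = (
            nf.curvature + nf.area + nf.area_stab + nf.proximity + nf.overlap
        )
        assert np.allclose(nf.total(), total)
        # proximity entry reproduces the standalone penalty
        assert np.allclose(nf.proximity, -proximity_penalty(c, nb, 4.0))
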