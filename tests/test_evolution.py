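"""Contour evolution, double-contour coupling and the frame loop."""

import numpy as np
import pytest

from beastrack.contour import (
    DoubleContour,
    contour_area,
    contour_mask,
    make_ellipse_contour,
)
from beastrack.energy import EnergyConfig
from beastrack.synthetic import SceneConfig, generate_scene, iou_score
from beastrack.tracking import (
    DescentConfig,
    evolve_contour,
    evolve_double,
    extract_signals,
    initialize_contours,
    segment_frame,
    track,
)


class TestDescentConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            DescentConfig(max_iterations=0)
        with pytest.raises(ValueError):
            DescentConfig(step_down=1.5)


class TestEvolveContour:
    def test_clean_disk_from_inside_and_outside(self, disk_image):
        cfg = EnergyConfig(rho=8, w_area=0, w_area_stab=0)
        for r0 in (15, 25):
            init = make_ellipse_contour((48, 48), (r0, r0), 0, 32)
            out, converged, _ = evolve_contour(
                disk_image, init, None, None, cfg, DescentConfig(max_iterations=100)
            )
            assert converged
            assert np.abs(out.node_radii - 20).mean() < 0.3

    def test_noisy_disk_boundary_recovery(self, noisy_disk):
        cfg = EnergyConfig(rho=8, w_area=0, w_area_stab=0)
        init = make_ellipse_contour((48, 48), (26, 26), 0, 32)
        out, _, _ = evolve_contour(
            noisy_disk, init, None, None, cfg, DescentConfig(max_iterations=100)
        )
        boundary_r = np.hypot(*(out.node_positions() - [48, 48]).T)
        assert np.abs(boundary_r - 20).mean() < 0.5

    def test_energy_not_increased(self, noisy_disk):
        cfg = EnergyConfig(rho=8)
        init = make_ellipse_contour((48, 48), (24, 24), 0, 32)
        _, _, e_half = evolve_contour(
            noisy_disk, init, None, None, cfg, DescentConfig(max_iterations=5)
        )
        _, _, e_full = evolve_contour(
            noisy_disk, init, None, None, cfg, DescentConfig(max_iterations=100)
        )
        # accepted-step energies are non-increasing, so a longer run can
        # never end higher than a shorter one
        assert e_full <= e_half + 1e-12

    def test_single_iteration_guard(self, disk_image):
        init = make_ellipse_contour((48, 48), (15, 15), 0, 32)
        out, _, _ = evolve_contour(
            disk_image, init, None, None, EnergyConfig(rho=8),
            DescentConfig(max_iterations=1, tolerance=100.0),
        )
        moved = np.abs(out.node_radii - init.node_radii).max()
        assert moved <= DescentConfig().initial_step + 1e-9

    def test_uniform_image_zero_weights_unchanged(self):
        img = np.full((96, 96), 0.5)
        cfg = EnergyConfig(w_kappa=0, w_area=0, w_area_stab=0, w_comp=0)
        init = make_ellipse_contour((48, 48), (15, 15), 0, 32)
        out, converged, _ = evolve_contour(img, init, None, None, cfg)
        assert converged
        assert np.allclose(out.node_radii, init.node_radii)
        assert np.allclose(out.pole, init.pole)


class TestEvolveDouble:
    def test_ring_cell_recovery(self, ring_image):
        dc = DoubleContour(
            make_ellipse_contour((48, 48), (4, 4), 0, 32),
            make_ellipse_contour((48, 48), (17, 17), 0, 32),
            margin=1.0,
        )
        cfg = EnergyConfig(rho=5, w_area=0, w_area_stab=0)
        out, _, _, low_contrast = evolve_double(
            ring_image, dc, (None, None), None, cfg,
            DescentConfig(max_iterations=150),
        )
        assert abs(out.nucleus.node_radii.mean() - 6) < 1.0
        assert abs(out.cytoplasm.node_radii.mean() - 14) < 1.0
        assert not low_contrast
        assert (out.cytoplasm.node_radii >= out.nucleus.node_radii + 1.0).all()

    def test_coupling_projection(self, ring_image):
        # cytoplasm initialized below the nucleus: ordering restored
        dc = DoubleContour(
            make_ellipse_contour((48, 48), (8, 8), 0, 32),
            make_ellipse_contour((48, 48), (5, 5), 0, 32),
            margin=1.0,
        )
        assert (dc.cytoplasm.node_radii >= dc.nucleus.node_radii + 1.0).all()
        out, _, _, _ = evolve_double(
            ring_image, dc, (None, None), None, EnergyConfig(rho=5),
            DescentConfig(max_iterations=1),
        )
        assert (out.cytoplasm.node_radii >= out.nucleus.node_radii + 1.0).all()

    def test_low_contrast_flag(self):
        img = np.full((96, 96), 0.5)
        dc = DoubleContour(
            make_ellipse_contour((48, 48), (6, 6), 0, 32),
            make_ellipse_contour((48, 48), (14, 14), 0, 32),
        )
        _, _, _, low_contrast = evolve_double(
            img, dc, (None, None), None, EnergyConfig(rho=5),
            DescentConfig(max_iterations=5),
        )
        assert low_contrast


class TestInitialize:
    def test_disk_with_inflated_ellipse(self, noisy_disk):
        cells = initialize_contours(
            noisy_disk, [(48, 48, 26, 26, 0.0)],
            energy_config=EnergyConfig(rho=8, w_area=0, w_area_stab=0),
        )
        assert np.abs(cells[0].node_radii - 20).mean() < 0.5

    def test_two_disjoint_disks_stay_disjoint(self):
        yy, xx = np.mgrid[0:96, 0:160]
        img = np.where(
            ((xx - 45) ** 2 + (yy - 48) ** 2 <= 400)
            | ((xx - 115) ** 2 + (yy - 48) ** 2 <= 400),
            1.0,
            0.1,
        )
        cells = initialize_contours(
            img, [(45, 48, 26, 26, 0.0), (115, 48, 26, 26, 0.0)]
        )
        m0 = contour_mask(cells[0], img.shape)
        m1 = contour_mask(cells[1], img.shape)
        assert (m0 & m1).sum() == 0

    def test_bad_ellipse_rejected(self, disk_image):
        with pytest.raises(ValueError):
            initialize_contours(disk_image, [(48, 48, -3, 5, 0.0)])
        with pytest.raises(ValueError):
            initialize_contours(disk_image, [(500, 48, 5, 5, 0.0)])


class TestSegmentFrame:
    def test_single_cell_matches_evolve_plus_recentre(self, disk_image):
        from beastrack.tracking import _recentre_cell

        cfg = EnergyConfig(rho=8, w_area=0, w_area_stab=0)
        dsc = DescentConfig(outer_sweeps=1)
        init = make_ellipse_contour((48, 48), (16, 16), 0, 32)
        cells, statuses = segment_frame(disk_image, [init], [None], cfg, dsc)
        direct, _, _ = evolve_contour(disk_image, init, None, [], cfg, dsc)
        direct = _recentre_cell(direct)
        assert statuses == ["tracked"]
        assert np.allclose(cells[0].node_radii, direct.node_radii, atol=1e-9)

    def test_requires_cells(self, disk_image):
        with pytest.raises(ValueError):
            segment_frame(disk_image, [], [], EnergyConfig())


class TestTrack:
    def test_static_scene_fixed_point(self):
        cfg = SceneConfig(
            n_frames=15, n_cells=4, seed=7, motion_amplitude=0.0,
            transients=None, blur_frames=[], noise_sd=0.0, overlap_factor=0.0,
            image_size=(192, 192),
        )
        stack, truth = generate_scene(cfg)
        ell = [
            (truth.centroids[c, 0, 0], truth.centroids[c, 0, 1], 16.1, 16.1, 0.0)
            for c in range(4)
        ]
        tracks = track(stack, ell, mode="one_layer")
        for tr in tracks:
            drift = np.linalg.norm(
                tr.outer(14).node_positions() - tr.outer(0).node_positions(),
                axis=1,
            ).mean()
            assert drift <= 0.5

    def test_moderate_motion_tracked(self):
        cfg = SceneConfig(
            n_frames=12, n_cells=2, seed=5, motion_coherence=1.0,
            blur_frames=[], transients=None,
        )
        stack, truth = generate_scene(cfg)
        ell = [
            (truth.centroids[c, 0, 0], truth.centroids[c, 0, 1], 16.1, 16.1, 0.0)
            for c in range(2)
        ]
        tracks = track(stack, ell, mode="one_layer", energy_config=EnergyConfig(rho=8))
        ious = [
            iou_score(contour_mask(tr.outer(t), stack.shape[1:]),
                      truth.cell_mask(t, tr.cell_id))
            for tr in tracks
            for t in range(12)
        ]
        assert np.mean(ious) >= 0.65

    def test_excessive_motion_loses_track(self):
        # jumps far beyond the band reach rho (and beyond any frame-to-frame
        # overlap of the cell) leave no image evidence within the bands: the
        # neighborhood radius bounds the detectable per-frame motion
        yy, xx = np.mgrid[0:96, 0:240]
        frames = []
        centers = [(30 + 36 * t, 48) for t in range(6)]
        for cx, cy in centers:
            frames.append(
                np.where((xx - cx) ** 2 + (yy - cy) ** 2 <= 100, 1.0, 0.1)
            )
        stack = np.stack(frames)
        tracks = track(stack, [(30, 48, 12, 12, 0.0)],
                       energy_config=EnergyConfig(rho=4))
        last_mask = contour_mask(tracks[0].outer(5), stack.shape[1:])
        truth_mask = (xx - centers[5][0]) ** 2 + (yy - 48) ** 2 <= 100
        assert iou_score(last_mask, truth_mask) < 0.3

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            track(np.zeros((0, 10, 10)), [(5, 5, 3, 3, 0.0)])

    def test_one_frame_stack(self, disk_image):
        tracks = track(disk_image[None], [(48, 48, 24, 24, 0.0)])
        assert len(tracks[0].contours) == 1
        assert tracks[0].status == ["tracked"]


class TestExtractSignals:
    def test_uniform_stack(self, disk_image):
        stack = np.full((3, 96, 96), 7.0)
        tracks = track(stack, [(48, 48, 15, 15, 0.0)])
        traces = extract_signals(stack, tracks)
        assert np.allclose(traces[0].values, 7.0)
        assert (traces[0].n_pixels > 0).all()

    def test_double_mode_excludes_nucleus(self, ring_image):
        # nucleus at 0.1, cytoplasm at 1.0: the double-contour trace reports
        # the cytoplasm level, not the disk-wide mean
        stack = np.stack([ring_image] * 2)
        tracks = track(stack, [(48, 48, 16, 16, 0.0)], mode="double",
                       energy_config=EnergyConfig(rho=5))
        traces = extract_signals(stack, tracks)
        assert traces[0].values[0] > 0.9
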