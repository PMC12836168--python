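import math
import warnings

import numpy as np
import pytest

from chemotaxgel import diffusion, geometry, synthetic_data as sd
from chemotaxgel.synthetic_data import (
    AgentParams,
    CellTypeProfile,
    generate_confluency_image,
    generate_tracer_stack,
    render_migration_frames,
    simulate_migration,
)


def _fit_from_stack(stack, layout):
    prof = diffusion.extract_line_profiles(stack, layout, "center")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prof = diffusion.normalize_profile(prof)
    return diffusion.fit_diffusion_coefficient(prof)


TIMES = [0.0, 600.0, 1200.0, 1800.0, 2400.0]


class TestTracerStacks:
    @pytest.mark.parametrize("true_d", [6.393, 0.6009])
    def test_noiseless_full_loop_recovery(self, aligned_layout, true_d):
        tracer = diffusion.TracerSpec("t", 1e4, true_d)
        stack = generate_tracer_stack(aligned_layout, tracer, TIMES)
        fit = _fit_from_stack(stack, aligned_layout)
        assert fit.D_hat == pytest.approx(true_d, rel=0.005)

    def test_same_seed_is_bit_identical(self, aligned_layout):
        tracer = diffusion.DEXTRAN_RHODAMINE_B
        a = generate_tracer_stack(aligned_layout, tracer, TIMES, noise_sigma=0.05, seed=5)
        b = generate_tracer_stack(aligned_layout, tracer, TIMES, noise_sigma=0.05, seed=5)
        assert np.array_equal(a.frames, b.frames)

    def test_noisy_recovery_median_error_under_10pct(self, aligned_layout):
        tracer = diffusion.TracerSpec("t", 1e4, 5.0)
        errs = []
        for seed in range(20):
            stack = generate_tracer_stack(
                aligned_layout, tracer, TIMES, noise_sigma=0.05, seed=seed
            )
            fit = _fit_from_stack(stack, aligned_layout)
            errs.append(abs(fit.D_hat - 5.0) / 5.0)
        assert np.median(errs) < 0.10

    def test_fast_tracer_flatter_profile_at_40_min(self, aligned_layout):
        # larger D keeps intensity near-uniform over the 500 µm transect
        drops = {}
        for tracer in (diffusion.DEXTRAN_RHODAMINE_B, diffusion.ALBUMIN_FITC):
            stack = generate_tracer_stack(aligned_layout, tracer, TIMES)
            prof = diffusion.extract_line_profiles(stack, aligned_layout, "center")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prof = diffusion.normalize_profile(prof)
            drops[tracer.true_D] = prof.intensities[0, -1] - prof.intensities[-1, -1]
        assert drops[6.393] < drops[0.6009]

    def test_fd_mode_uses_simulator_fields(self, aligned_layout):
        tracer = diffusion.TracerSpec("t", 1e4, 6.393)
        stack = generate_tracer_stack(
            aligned_layout, tracer, [0.0, 600.0], mode="fd", grid_spacing=40.0
        )
        # mass conservation carries over from the simulator
        assert stack.frames[1].sum() == pytest.approx(stack.frames[0].sum(), rel=1e-6)

    def test_ground_truth_in_metadata(self, aligned_layout):
        stack = generate_tracer_stack(aligned_layout, diffusion.ALBUMIN_FITC, TIMES)
        assert stack.metadata["true_D_um2_s"] == 0.6009


class TestMigrationSimulator:
    def test_zero_speed_trajectories_constant(self, paper_layout):
        ct = CellTypeProfile("still", AgentParams(speed=0.0, n_agents=20), "outer0")
        traj = simulate_migration(paper_layout, [ct], duration=10 * 1800.0, seed=1)["still"]
        assert np.array_equal(traj[0], traj[-1])

    def test_non_motile_types_do_not_move(self, paper_layout):
        ct = CellTypeProfile(
            "fixed", AgentParams(speed=12.0, n_agents=20, motile=False), "outer1"
        )
        traj = simulate_migration(paper_layout, [ct], duration=10 * 1800.0, seed=1)["fixed"]
        assert np.array_equal(traj[0], traj[-1])

    def test_agents_start_on_their_well_rim(self, paper_layout):
        ct = CellTypeProfile("c", AgentParams(n_agents=50), "outer2")
        traj = simulate_migration(paper_layout, [ct], duration=1800.0, seed=2)["c"]
        wx, wy = paper_layout.well_position("outer2")
        radii = np.hypot(traj[0, :, 0] - wx, traj[0, :, 1] - wy)
        assert np.allclose(radii, paper_layout.well_radius)

    def test_unbiased_walk_has_no_mean_drift(self, paper_layout):
        # 50 seeds x 100 agents: mean displacement within 3 SE of zero
        disp = []
        for seed in range(50):
            ct = CellTypeProfile(
                "c", AgentParams(n_agents=100, chemotactic_bias=0.0), "outer0"
            )
            traj = simulate_migration(paper_layout, [ct], duration=24 * 1800.0, seed=seed)["c"]
            disp.append(traj[-1] - traj[0])
        disp = np.concatenate(disp)
        se = disp.std(axis=0) / math.sqrt(len(disp))
        mean = disp.mean(axis=0)
        assert abs(mean[0]) < 3 * se[0]
        assert abs(mean[1]) < 3 * se[1]

    def test_strong_bias_drives_agents_toward_center(self, paper_layout):
        # displacement projected on the rim->center bearing positive in >=95% of seeds
        wx, wy = paper_layout.well_position("outer0")
        cx, cy = paper_layout.center_well_position
        bearing = np.array([cx - wx, cy - wy])
        bearing = bearing / np.linalg.norm(bearing)
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            ct = CellTypeProfile(
                "c", AgentParams(n_agents=30, chemotactic_bias=8.0), "outer0"
            )
            traj = simulate_migration(paper_layout, [ct], duration=24 * 1800.0, seed=seed)["c"]
            mean_disp = (traj[-1] - traj[0]).mean(axis=0)
            wins += float(mean_disp @ bearing) > 0
        assert wins >= 0.95 * n_seeds

    def test_reflecting_boundaries_keep_agents_inside(self):
        layout = geometry.build_layout(400.0, 300.0, (2200.0, 2200.0), pixel_size=10.0)
        ct = CellTypeProfile("c", AgentParams(speed=80.0, n_agents=40), "outer0")
        traj = simulate_migration(layout, [ct], duration=48 * 1800.0, seed=3)["c"]
        w, h = layout.chamber_extent
        assert traj[..., 0].min() >= 0 and traj[..., 0].max() <= w
        assert traj[..., 1].min() >= 0 and traj[..., 1].max() <= h


class TestRendering:
    def test_zero_agents_renders_constant_background(self, paper_layout):
        traj = np.empty((3, 0, 2))
        stack, truth = render_migration_frames(traj, paper_layout, (64, 64))
        assert np.allclose(stack.frames, 200.0)
        assert not truth.any()

    def test_truth_mask_area_matches_blob_geometry(self, paper_layout):
        # well-separated blobs: mask area equals n * pi * r^2 within 2%
        ps = paper_layout.pixel_size
        pts = np.array([[500.0, 500.0], [1500.0, 500.0], [500.0, 1500.0], [1500.0, 1500.0]])
        traj = pts[None]
        stack, truth = render_migration_frames(
            traj, paper_layout, (220, 220), blob_radius_um=120.0
        )
        r_px = 120.0 / ps
        assert truth[0].sum() == pytest.approx(4 * math.pi * r_px**2, rel=0.02)

    def test_rendering_deterministic_given_trajectories(self, paper_layout):
        rng = np.random.default_rng(0)
        traj = rng.uniform(200, 1800, (2, 10, 2))
        a, _ = render_migration_frames(traj, paper_layout, (128, 128))
        b, _ = render_migration_frames(traj, paper_layout, (128, 128))
        assert np.array_equal(a.frames, b.frames)


class TestConfluencyGenerator:
    def test_zero_target_is_blank(self):
        img, mask = generate_confluency_image((128, 128), 0.0, seed=1)
        assert not mask.any()
        assert img.dtype == np.uint8

    def test_hits_target_fraction_within_half_point(self):
        img, mask = generate_confluency_image((512, 512), 0.83, seed=2)
        assert 0.825 <= mask.mean() <= 0.835

    def test_same_seed_identical_outputs(self):
        a_img, a_mask = generate_confluency_image((128, 128), 0.4, seed=9)
        b_img, b_mask = generate_confluency_image((128, 128), 0.4, seed=9)
        assert np.array_equal(a_img, b_img) and np.array_equal(a_mask, b_mask)

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError, match="0.99"):
            generate_confluency_image((64, 64), 0.999, seed=0)


class TestDirectionalDetection:
    def test_biased_wells_beat_controls(self):
        # a reduced version of the power experiment: biased vs control wells
        res = sd.directional_detection_experiment(n_runs=3, seed=11, kappa=2.0)
        assert res["rejection_rate"] == 1.0

    def test_specificity_non_motile_wells_produce_no_signal(self, paper_layout):
        aligned = sd.pixel_aligned_layout(paper_layout)
        bias = sd.simulate_well_assay(aligned, kappa=0.0, seed=5, speed=0.0)
        # nothing leaves the excluded well body: no migrated area at all
        assert math.isnan(bias)

    def test_faster_cells_migrate_more_area(self, paper_layout):
        # ordering property: larger motility -> larger migrated area
        from chemotaxgel import migration_quant as mq

        aligned = sd.pixel_aligned_layout(paper_layout)
        totals = {}
        for speed in (5.0, 20.0):
            ct = CellTypeProfile(
                "c", AgentParams(speed=speed, n_agents=60), "outer0"
            )
            traj = simulate_migration(aligned, [ct], duration=72 * 1800.0, seed=21)["c"]
            rc = aligned.well_center_px("outer0")
            side = 300
            origin = (round(rc[0] - (side - 1) / 2), round(rc[1] - (side - 1) / 2))
            _, truth = render_migration_frames(
                traj, aligned, (side, side), time_indices=[len(traj) - 1], origin_px=origin
            )
            qa = mq.quadrant_migration_areas(truth[0], 1.05 * aligned.well_radius_px)
            totals[speed] = qa.total_fraction
        assert totals[20.0] > totals[5.0]
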