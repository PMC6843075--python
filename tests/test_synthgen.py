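"""Generator-side guarantees: determinism, ground-truth consistency,
and the scene geometry the downstream analyses assume."""

import numpy as np
import pytest

from spheromotion.synthgen import (
    LiveDeadSpec,
    PopSpec,
    SceneConfig,
    ShellSpec,
    SpheroidSpec,
    calibrate_truncnorm_mu,
    make_cohort,
    make_livedead_scene,
    make_popping_series,
    make_rotating_movie,
    make_shell_stack,
    sample_cohort_omegas,
)


class TestRotatingMovie:
    def test_static_spheroid_frames_identical_up_to_noise(self):
        scene = SceneConfig(duration_h=0.5, noise_sigma=0.0, drift_um_per_h=0.0, seed=1)
        movie, truth = make_rotating_movie(scene, SpheroidSpec(omega_rev_h=0.0))
        assert truth.true_values["omega_rev_h"] == 0.0
        ref = movie.frames[0].astype(float)
        for f in movie.frames[1:]:
            # frames differ only by the +-5% per-frame intensity jitter
            ratio = f[ref > 100].astype(float) / ref[ref > 100]
            assert ratio.std() < 0.01

    def test_step_angle_matches_rate_conversion(self):
        scene = SceneConfig(frame_interval_min=5.0, duration_h=1.0, seed=2)
        _, truth = make_rotating_movie(scene, SpheroidSpec(omega_rev_h=0.26))
        # 0.26 rev/h * 360 deg / 12 intervals per hour
        assert truth.true_values["step_deg"] == pytest.approx(7.8)

    def test_same_config_and_seed_bit_identical(self):
        scene = SceneConfig(duration_h=0.5, seed=33)
        m1, t1 = make_rotating_movie(scene, SpheroidSpec())
        m2, t2 = make_rotating_movie(scene, SpheroidSpec())
        np.testing.assert_array_equal(m1.frames, m2.frames)
        assert t1.true_values == t2.true_values

    def test_undersized_spheroid_rejected(self):
        scene = SceneConfig(pixel_size_um=4.0, duration_h=0.5)
        with pytest.raises(ValueError, match="pixel"):
            make_rotating_movie(scene, SpheroidSpec(diameter_um=12.0))

    def test_frame_count_from_duration(self):
        scene = SceneConfig(duration_h=1.0, frame_interval_min=5.0, seed=3)
        movie, _ = make_rotating_movie(scene, SpheroidSpec())
        assert movie.n_frames == 13  # 12 intervals + initial frame


class TestShellStack:
    def test_full_coverage_is_closed_shell(self, full_shell_stack):
        stack, truth = full_shell_stack
        assert truth.true_values["marker_voxels"] == truth.true_values["shell_voxels"]

    def test_zero_coverage_no_marker_above_background(self):
        scene = SceneConfig(seed=4, noise_sigma=0.0)
        stack, truth = make_shell_stack(
            scene, ShellSpec(radius_um=10, shell_thickness_um=2, coverage_fraction=0.0)
        )
        assert truth.true_values["marker_voxels"] == 0
        marker = stack.channel(1)
        assert marker.max() == marker.min()

    def test_half_coverage_half_the_marker_voxels(self):
        scene = SceneConfig(seed=5, noise_sigma=0.0)
        kwargs = dict(radius_um=10, shell_thickness_um=2)
        _, t_full = make_shell_stack(scene, ShellSpec(coverage_fraction=1.0, **kwargs))
        _, t_half = make_shell_stack(
            scene, ShellSpec(coverage_fraction=0.5, patch_count=8, **kwargs)
        )
        ratio = t_half.true_values["marker_voxels"] / t_full.true_values["marker_voxels"]
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_too_thin_shell_advises_voxel_reduction(self):
        scene = SceneConfig(pixel_size_um=2.0)
        with pytest.raises(ValueError, match="voxel"):
            make_shell_stack(scene, ShellSpec(shell_thickness_um=1.0))


class TestLiveDead:
    def test_exact_dead_count_at_fixed_seed(self):
        scene = SceneConfig(seed=6)
        spec = LiveDeadSpec(n_cells=100, dead_fraction=0.26)
        _, truth = make_livedead_scene(scene, spec)
        assert truth.true_values["n_dead"] == 26
        states = truth.detail["cell_state"]
        assert np.count_nonzero(states == "dead") == 26

    def test_zero_dead_fraction_empty_dead_channel(self):
        scene = SceneConfig(seed=7, noise_sigma=0.0)
        stack, truth = make_livedead_scene(
            scene, LiveDeadSpec(n_cells=20, dead_fraction=0.0)
        )
        assert truth.true_values["n_dead"] == 0
        dead = stack.channel(1)
        assert dead.max() == dead.min()

    def test_all_singles_distribution_gives_zero_clustered(self):
        scene = SceneConfig(seed=8)
        _, truth = make_livedead_scene(
            scene,
            LiveDeadSpec(n_cells=30, dead_fraction=0.1, cluster_size_distribution={1: 1.0}),
        )
        assert truth.true_values["clustered_fraction"] == 0.0

    def test_dead_cells_are_always_single(self):
        scene = SceneConfig(seed=9)
        _, truth = make_livedead_scene(scene, LiveDeadSpec(n_cells=60))
        states = truth.detail["cell_state"]
        structs = truth.detail["cell_struct"]
        for s in np.unique(structs[states == "dead"]):
            assert np.count_nonzero(structs == s) == 1

    def test_packing_failure_reported(self):
        scene = SceneConfig(seed=10)
        with pytest.raises(ValueError, match="packing"):
            make_livedead_scene(
                scene,
                LiveDeadSpec(n_cells=100, min_separation_um=40.0, box_side_um=100.0),
            )


class TestPoppingSeries:
    def test_single_cycle_volume_ratio_is_expansion(self):
        spec = PopSpec(n_cycles=1, expansion_percent=42.8)
        _, truth = make_popping_series(spec, seed=11)
        assert truth.true_values["volume_ratio_terminal"] == pytest.approx(1.428)

    def test_cycle_boundaries_spacing(self):
        # 0.67 h cycles at 5-min sampling: boundaries ~8 samples apart
        spec = PopSpec(n_cycles=3, cycle_duration_h=0.67, sampling_interval_min=5.0)
        _, truth = make_popping_series(spec, seed=12)
        durations = np.array(truth.true_values["cycle_durations_h"])
        samples = durations * 60 / 5.0
        assert np.all(np.abs(samples - 8) <= 1)

    def test_unresolvable_sampling_rejected(self):
        with pytest.raises(ValueError, match="unresolvable"):
            make_popping_series(
                PopSpec(cycle_duration_h=0.05, sampling_interval_min=5.0), seed=13
            )

    def test_deterministic_per_seed(self):
        df1, t1 = make_popping_series(PopSpec(duration_sd_h=0.1), seed=14)
        df2, t2 = make_popping_series(PopSpec(duration_sd_h=0.1), seed=14)
        assert df1.equals(df2)
        assert t1.true_values["cycle_durations_h"] == t2.true_values["cycle_durations_h"]


class TestCohort:
    def test_cardinality_and_manifest(self):
        scene = SceneConfig(duration_h=0.25)
        pairs = make_cohort("demo", 5, 0.28, 0.1, scene, seed=15)
        assert len(pairs) == 5
        assert len({t.scene_id for _, t in pairs}) == 5

    def test_zero_sd_gives_constant_truth(self):
        scene = SceneConfig(duration_h=0.25)
        pairs = make_cohort("const", 4, 0.2, 0.0, scene, seed=16)
        assert all(t.true_values["omega_rev_h"] == pytest.approx(0.2) for _, t in pairs)

    def test_truncation_keeps_rates_nonnegative(self, rng):
        vals = sample_cohort_omegas(200, 0.04, 0.061, rng, sampling="iid")
        assert np.all(vals >= 0)

    def test_stratified_sampling_pins_mean_at_operating_point(self, rng):
        vals = sample_cohort_omegas(37, 0.04, 0.061, rng)
        assert np.all(vals >= 0)
        assert vals.mean() == pytest.approx(0.04, abs=0.002)

    def test_truncnorm_calibration_recovers_target_mean(self):
        from scipy.stats import truncnorm

        mu = calibrate_truncnorm_mu(0.04, 0.061)
        got = truncnorm.mean((0 - mu) / 0.061, np.inf, loc=mu, scale=0.061)
        assert got == pytest.approx(0.04, abs=1e-9)
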