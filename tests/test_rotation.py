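"""Rotation registration and angular-velocity tracking."""

import numpy as np
import pytest
from scipy import ndimage

from spheromotion.rotation import (
    IndeterminateCoordinationError,
    RotationTrack,
    UnresolvableRotationError,
    is_coordinated,
    omega_from_rate,
    register_rotation,
    track_rotation,
)
from spheromotion.segment import segment_frame
from spheromotion.synthgen import SceneConfig, SpheroidSpec, make_rotating_movie


def _center(movie):
    ms = max(
        segment_frame(movie.frames[0], movie.pixel_size_um),
        key=lambda s: s.equivalent_diameter_um,
    )
    return ms.centroid_px


class TestRegisterRotation:
    def test_identity_registers_near_zero(self, clean_short_movie):
        movie, _ = clean_short_movie
        c = _center(movie)
        assert register_rotation(movie.frames[0], movie.frames[0], c) == pytest.approx(
            0.0, abs=0.2
        )

    def test_known_rotation_recovered_with_independent_transform(self, clean_short_movie):
        # oracle: scipy.ndimage.rotate applies a known in-plane rotation
        movie, _ = clean_short_movie
        f0 = movie.frames[0].astype(float)
        c = (f0.shape[0] // 2, f0.shape[1] // 2)
        rotated = ndimage.rotate(f0, 7.5, reshape=False, order=3)
        assert register_rotation(f0, rotated, c) == pytest.approx(7.5, abs=0.5)

    def test_generator_step_recovered_with_sign(self, clean_short_movie):
        movie, truth = clean_short_movie
        c = _center(movie)
        step = register_rotation(movie.frames[0], movie.frames[1], c)
        assert step == pytest.approx(truth.true_values["step_deg"], abs=0.5)

    def test_antisymmetry(self, clean_short_movie):
        movie, _ = clean_short_movie
        c = _center(movie)
        fwd = register_rotation(movie.frames[0], movie.frames[1], c)
        bwd = register_rotation(movie.frames[1], movie.frames[0], c)
        assert fwd == pytest.approx(-bwd, abs=0.5)

    def test_featureless_structure_unresolvable(self):
        yy, xx = np.mgrid[:81, :81]
        disk = (np.hypot(yy - 40, xx - 40) <= 25).astype(float)
        with pytest.raises(UnresolvableRotationError):
            register_rotation(disk, disk, (40, 40))

    def test_intensity_invariance(self, clean_short_movie):
        movie, _ = clean_short_movie
        c = _center(movie)
        a = register_rotation(movie.frames[0], movie.frames[1], c)
        b = register_rotation(
            movie.frames[0] * 3.7, movie.frames[1].astype(float) * 3.7, c
        )
        assert a == pytest.approx(b, abs=1e-6)


class TestOmegaConversion:
    @pytest.mark.parametrize(
        "rate,expected", [(92.0, 0.26), (360.0, 1.0), (0.0, 0.0)]
    )
    def test_rate_to_rev_per_hour(self, rate, expected):
        assert round(omega_from_rate(rate), 2) == expected

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            omega_from_rate(-1.0)


class TestTrackRotation:
    def test_noise_free_recovery_within_5_percent(self):
        scene = SceneConfig(noise_sigma=0.0, drift_um_per_h=0.0, seed=404)
        movie, truth = make_rotating_movie(scene, SpheroidSpec(omega_rev_h=1.0))
        track = track_rotation(movie)
        assert track.omega_rev_h == pytest.approx(1.0, rel=0.05)
        assert track.direction == "CCW"

    def test_default_noise_recovery_within_10_percent(self, default_noise_movie):
        movie, truth = default_noise_movie
        track = track_rotation(movie)
        assert track.omega_rev_h == pytest.approx(
            truth.true_values["omega_rev_h"], rel=0.10
        )

    def test_static_movie_mixed_direction(self):
        scene = SceneConfig(duration_h=1.0, seed=405)
        movie, _ = make_rotating_movie(scene, SpheroidSpec(omega_rev_h=0.0))
        track = track_rotation(movie)
        assert track.omega_rev_h < 0.01
        assert track.direction == "mixed"

    def test_translation_invariance(self):
        base = SceneConfig(noise_sigma=0.0, drift_um_per_h=0.0, duration_h=4.0, seed=406)
        drifted = SceneConfig(
            noise_sigma=0.0, drift_um_per_h=1.5, duration_h=4.0, seed=406
        )
        sph = SpheroidSpec(omega_rev_h=0.3)
        t0 = track_rotation(make_rotating_movie(base, sph)[0])
        t1 = track_rotation(make_rotating_movie(drifted, sph)[0])
        assert t1.omega_rev_h == pytest.approx(t0.omega_rev_h, rel=0.02)

    def test_time_reversal_negates_cumulative_angle(self, clean_short_movie):
        movie, _ = clean_short_movie
        fwd = track_rotation(movie)
        rev_movie = type(movie)(
            movie.frames[::-1].copy(), movie.pixel_size_um, movie.frame_interval_min
        )
        rev = track_rotation(rev_movie)
        assert rev.cumulative_deg == pytest.approx(-fwd.cumulative_deg, abs=1.0)
        assert rev.omega_rev_h == pytest.approx(fwd.omega_rev_h, rel=0.02)

    def test_lost_structure_truncates_with_warning(self, clean_short_movie):
        movie, _ = clean_short_movie
        frames = movie.frames.copy()
        frames[8:] = 0
        broken = type(movie)(frames, movie.pixel_size_um, movie.frame_interval_min)
        with pytest.warns(UserWarning, match="truncated"):
            track = track_rotation(broken)
        assert track.truncated
        assert track.n_steps == 7


class TestIsCoordinated:
    @staticmethod
    def make_track(steps, residuals=None):
        steps = np.asarray(steps, dtype=float)
        return RotationTrack(
            structure_label=1,
            step_angles_deg=steps,
            interval_min=5.0,
            omega_rev_h=0.0,
            direction="CCW",
            coordinated=False,
            step_residuals=np.asarray(
                residuals if residuals is not None else np.zeros_like(steps)
            ),
        )

    def test_uniform_steps_coordinated(self):
        assert is_coordinated(self.make_track([7.5] * 10))

    def test_alternating_signs_not_coordinated(self):
        assert not is_coordinated(self.make_track([7.5, -7.5] * 5))

    def test_high_residual_not_coordinated(self):
        track = self.make_track([7.5] * 10, residuals=[0.5] * 10)
        assert not is_coordinated(track, residual_max=0.15)

    def test_too_few_steps_indeterminate(self):
        with pytest.raises(IndeterminateCoordinationError):
            is_coordinated(self.make_track([7.5] * 4))

    def test_independent_cell_motion_fails_residual(self):
        scene = SceneConfig(duration_h=2.0, seed=407)
        movie, _ = make_rotating_movie(
            scene, SpheroidSpec(omega_rev_h=0.28, cell_jitter_um=4.0)
        )
        track = track_rotation(movie)
        assert not track.coordinated
        assert np.median(track.step_residuals) > 0.15
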