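"""Phase segmentation, pop detection and peripheral localization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spheromotion.morphodynamics import (
    IndeterminatePeripheralError,
    detect_pops,
    ellipsoid_volume,
    expansion_percent,
    peripheral_fraction,
    segment_phases,
)
from spheromotion.synthgen import PopSpec, make_popping_series


def flat_series(n=30, level=50.0, dt=5 / 60):
    t = np.arange(n) * dt
    return pd.DataFrame({"time_h": t, "major_um": level * 1.1, "minor_um": [level] * n})


class TestEllipsoidVolume:
    def test_sphere_closed_form(self):
        assert ellipsoid_volume(20, 20) == pytest.approx(4 / 3 * math.pi * 1000)

    def test_prolate_closed_form(self):
        assert ellipsoid_volume(30, 20) == pytest.approx(6283.19, abs=0.01)

    def test_mean_cluster_scale(self):
        # a 26-um sphere sits near the reported mean cluster volume scale
        assert ellipsoid_volume(26, 26) == pytest.approx(9202.77, abs=0.01)

    def test_axis_order_enforced(self):
        with pytest.raises(ValueError):
            ellipsoid_volume(20, 30)

    @settings(deadline=None, derandomize=True)
    @given(
        major=st.floats(10, 100),
        ratio=st.floats(0.3, 1.0),
        k=st.floats(0.5, 3.0),
    )
    def test_homogeneous_degree_three(self, major, ratio, k):
        v1 = ellipsoid_volume(major, major * ratio)
        v2 = ellipsoid_volume(k * major, k * major * ratio)
        assert v2 == pytest.approx(k**3 * v1, rel=1e-9)


class TestSegmentPhases:
    def test_monotone_series_single_tensile_segment(self):
        t = np.arange(20) * 0.1
        major = 30 * np.exp(0.3 * t)  # ~30%/h volume growth per axis scale
        series = pd.DataFrame({"time_h": t, "major_um": major, "minor_um": major * 0.9})
        segs = segment_phases(series)
        assert [s.kind for s in segs] == ["tensile"]

    def test_constant_series_single_contractile_segment(self):
        segs = segment_phases(flat_series())
        assert len(segs) == 1
        assert segs[0].kind == "contractile"
        assert segs[0].mean_rate_um3_per_h == pytest.approx(0.0, abs=1e-6)

    def test_generated_three_cycles_six_alternating_segments(self):
        series, _ = make_popping_series(PopSpec(axis_noise_rel=0.0), seed=31)
        segs = segment_phases(series)
        kinds = [s.kind for s in segs]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))  # alternating
        assert abs(len(segs) - 6) <= 1

    def test_segments_tile_series_without_overlap(self):
        series, _ = make_popping_series(PopSpec(), seed=32)
        segs = segment_phases(series)
        for a, b in zip(segs, segs[1:]):
            assert b.t0_h > a.t1_h
        assert segs[0].t0_h == series["time_h"].iloc[0]
        assert segs[-1].t1_h == series["time_h"].iloc[-1]

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            segment_phases(flat_series(n=4))


class TestDetectPops:
    def test_flat_series_no_pops(self):
        assert detect_pops(flat_series()) == []

    def test_single_pop_recovers_expansion(self):
        series, truth = make_popping_series(
            PopSpec(n_cycles=1, expansion_percent=42.8), seed=33
        )
        cycles = detect_pops(series)
        assert len(cycles) == 1
        assert cycles[0].expansion_percent == pytest.approx(42.8, abs=3.0)

    def test_three_cycles_duration_recovered(self):
        series, truth = make_popping_series(
            PopSpec(n_cycles=3, cycle_duration_h=0.67), seed=34
        )
        cycles = detect_pops(series)
        assert len(cycles) == 3
        mean_dur = np.mean([c.duration_h for c in cycles])
        true_dur = np.mean(truth.true_values["cycle_durations_h"])
        assert mean_dur == pytest.approx(true_dur, abs=0.1)

    def test_recovery_over_seeded_series(self):
        # |bias| <= 3 points on expansion, <= 2 sampling intervals on duration
        spec = PopSpec(duration_sd_h=0.15, expansion_sd_percent=8.3)
        exp_err, dur_err = [], []
        for seed in range(20):
            series, truth = make_popping_series(spec, seed=seed)
            cycles = detect_pops(series)
            if not cycles:
                continue
            exp_err.append(
                np.mean([c.expansion_percent for c in cycles])
                - np.mean(truth.true_values["expansion_percents"])
            )
            dur_err.append(
                np.mean([c.duration_h for c in cycles])
                - np.mean(truth.true_values["cycle_durations_h"])
            )
        assert len(exp_err) >= 18
        assert abs(np.mean(exp_err)) <= 3.0
        assert abs(np.mean(dur_err)) <= 2 * 5 / 60


class TestExpansionPercent:
    @pytest.mark.parametrize(
        "vb,va,expected", [(1000, 1000, 0.0), (1000, 1428, 42.8), (1000, 1330, 33.0)]
    )
    def test_closed_form(self, vb, va, expected):
        assert expansion_percent(vb, va) == pytest.approx(expected)

    def test_unit_invariance(self):
        assert expansion_percent(1.0, 1.428) == pytest.approx(
            expansion_percent(1000.0, 1428.0)
        )

    def test_nonpositive_before_rejected(self):
        with pytest.raises(ValueError):
            expansion_percent(0.0, 10.0)


class TestPeripheralFraction:
    def test_all_at_surface(self):
        pos = np.array([[10.0, 0, 0], [0, 10.0, 0], [0, 0, -10.0]])
        assert peripheral_fraction(pos, (0, 0, 0), 10.0) == 1.0

    def test_all_at_centroid(self):
        pos = np.zeros((5, 3))
        assert peripheral_fraction(pos, (0, 0, 0), 10.0) == 0.0

    def test_uniform_sphere_matches_volume_ratio(self, rng):
        # P(r >= 0.8 R) = 1 - 0.8^3 = 0.488 for uniform positions in a ball
        n = 1000
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = 10.0 * rng.uniform(size=n) ** (1 / 3)
        pos = u * r[:, None]
        frac = peripheral_fraction(pos, (0, 0, 0), 10.0, shell_fraction=0.2)
        assert frac == pytest.approx(1 - 0.8**3, abs=0.05)

    def test_no_positives_indeterminate(self):
        with pytest.raises(IndeterminatePeripheralError):
            peripheral_fraction(np.empty((0, 3)), (0, 0, 0), 10.0)
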