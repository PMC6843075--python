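"""Popping morphodynamics: phases, expansion events, peripheral statistics.

Growing structures alternate contractile ("thick" basement membrane)
phases with tensile ("thin") phases that end in a rapid volumetric
expansion when the membrane fails — a "pop". This module segments
major/minor-axis time series into those phases, detects pops, and
quantifies the cycle duration (h) and the volumetric expansion (%)
between the plateaus flanking each pop.

Volume convention: prolate ellipsoid from the two measured axes,
V = (4/3)π (major/2)(minor/2)²; an oblate alternative is provided since
only two axes are observed and the choice is a convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

DEFAULT_SMOOTH_WINDOW = 3
DEFAULT_RATE_THRESHOLD = 30.0  # % volume per hour; pops are far faster
DEFAULT_RATE_DEADBAND = 8.0  # % per hour treated as zero rate (tie => contractile)
DEFAULT_SHELL_FRACTION = 0.25


class IndeterminatePeripheralError(ValueError):
    """No marker-positive positions: a peripheral fraction is undefined."""


@dataclass
class PhaseSegment:
    """One contractile or tensile interval of a volume series."""

    t0_h: float
    t1_h: float
    kind: str  # 'contractile' | 'tensile'
    mean_rate_um3_per_h: float


@dataclass
class PoppingCycle:
    """One contraction→pop cycle with flanking plateau volumes."""

    start_h: float
    pop_h: float
    end_h: float
    v_before_um3: float
    v_after_um3: float

    def __post_init__(self) -> None:
        if not self.start_h < self.pop_h <= self.end_h:
            raise ValueError("cycle boundaries must satisfy start < pop <= end")
        if self.expansion_percent <= 0:
            raise ValueError("a detected pop must expand the structure")

    @property
    def duration_h(self) -> float:
        return self.end_h - self.start_h

    @property
    def expansion_percent(self) -> float:
        return expansion_percent(self.v_before_um3, self.v_after_um3)


def ellipsoid_volume(major_um: float, minor_um: float, convention: str = "prolate") -> float:
    """Ellipsoid volume (um³) from major/minor axis lengths (um).

    prolate: V = (4/3)π (a/2)(b/2)²; oblate: V = (4/3)π (a/2)²(b/2).
    """
    if major_um <= 0 or minor_um <= 0:
        raise ValueError("axes must be > 0")
    if minor_um > major_um + 1e-9:
        raise ValueError("minor axis exceeds major axis")
    a, b = major_um / 2.0, minor_um / 2.0
    if convention == "prolate":
        return 4.0 / 3.0 * math.pi * a * b * b
    if convention == "oblate":
        return 4.0 / 3.0 * math.pi * a * a * b
    raise ValueError(f"unknown convention: {convention}")


def volume_series(series: pd.DataFrame, convention: str = "prolate") -> np.ndarray:
    major = np.asarray(series["major_um"], dtype=float)
    minor = np.asarray(series["minor_um"], dtype=float)
    return np.array(
        [ellipsoid_volume(a, b, convention) for a, b in zip(major, minor)]
    )


def _smoothed_volume(series: pd.DataFrame, smooth_window: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(series["time_h"], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time_h must be strictly increasing")
    v = volume_series(series)
    if smooth_window > 1:
        v = median_filter(v, size=smooth_window, mode="nearest")
    return t, v


def segment_phases(
    series: pd.DataFrame,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    rate_deadband_percent_per_h: float = DEFAULT_RATE_DEADBAND,
) -> list[PhaseSegment]:
    """Partition a series into alternating contractile/tensile segments.

    The volume series is median-smoothed, the relative volume rate is
    taken by central differences, and samples are classed tensile when the
    rate exceeds the dead band and contractile otherwise (zero-rate ties
    resolve to contractile). Adjacent same-kind runs merge; segments tile
    the series with no gaps.
    """
    if len(series) < 5:
        raise ValueError("at least 5 samples are needed to segment phases")
    t, v = _smoothed_volume(series, smooth_window)
    # centered relative rate, %/h
    rate = np.gradient(v, t) / v * 100.0
    kinds = np.where(rate > rate_deadband_percent_per_h, "tensile", "contractile")

    segments: list[PhaseSegment] = []
    start = 0
    for i in range(1, len(kinds) + 1):
        if i == len(kinds) or kinds[i] != kinds[start]:
            t0, t1 = t[start], t[i - 1] if i - 1 > start else t[start]
            # absolute mean rate over the run
            dt = t[min(i - 1, len(t) - 1)] - t[start]
            mean_rate = (v[i - 1] - v[start]) / dt if dt > 0 else 0.0
            segments.append(
                PhaseSegment(
                    t0_h=float(t0),
                    t1_h=float(t[i - 1]),
                    kind=str(kinds[start]),
                    mean_rate_um3_per_h=float(mean_rate),
                )
            )
            start = i
    return segments


def expansion_percent(v_before: float, v_after: float) -> float:
    """Relative volumetric expansion, 100·(v_after − v_before)/v_before."""
    if v_before <= 0:
        raise ValueError("v_before must be > 0")
    return 100.0 * (v_after - v_before) / v_before


def detect_pops(
    series: pd.DataFrame,
    rate_threshold_percent_per_h: float = DEFAULT_RATE_THRESHOLD,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> list[PoppingCycle]:
    """Detect popping cycles in an axis series.

    A pop is a tensile segment whose mean relative volume rate exceeds the
    threshold; the flanking volumes are medians over the neighbouring
    contractile plateaus, and a cycle spans from the start of the
    preceding contractile phase to the end of the pop. Tensile segments at
    the very start or end of the series (no flanking plateau) are skipped.
    """
    segments = segment_phases(series, smooth_window)
    t, v = _smoothed_volume(series, smooth_window)
    cycles: list[PoppingCycle] = []
    prev_pop_end: float | None = None
    for i, seg in enumerate(segments):
        if seg.kind != "tensile":
            continue
        sel = (t >= seg.t0_h) & (t <= seg.t1_h)
        vv = v[sel]
        tt = t[sel]
        if vv.size < 2:
            continue
        rel_rate = (vv[-1] - vv[0]) / (tt[-1] - tt[0]) / np.median(vv) * 100.0
        if rel_rate <= rate_threshold_percent_per_h:
            continue
        if i == 0 or i == len(segments) - 1:
            continue
        before = segments[i - 1]
        after = segments[i + 1]
        v_before = float(np.median(v[(t >= before.t0_h) & (t <= before.t1_h)]))
        v_after = float(np.median(v[(t >= after.t0_h) & (t <= after.t1_h)]))
        if v_after <= v_before:
            continue
        # cycles run pop-to-pop: after the first, a cycle starts where the
        # previous pop ended rather than at the (one sample later) start
        # of the contractile run
        start = prev_pop_end if prev_pop_end is not None else before.t0_h
        cycles.append(
            PoppingCycle(
                start_h=start,
                pop_h=seg.t0_h,
                end_h=seg.t1_h,
                v_before_um3=v_before,
                v_after_um3=v_after,
            )
        )
        prev_pop_end = seg.t1_h
    return cycles


def cycles_table(cycles: list[PoppingCycle]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_h": c.start_h,
                "pop_h": c.pop_h,
                "end_h": c.end_h,
                "duration_h": c.duration_h,
                "expansion_percent": c.expansion_percent,
            }
            for c in cycles
        ],
        columns=["start_h", "pop_h", "end_h", "duration_h", "expansion_percent"],
    )


def peripheral_fraction(
    marker_positions: np.ndarray,
    centroid,
    radius_um: float,
    shell_fraction: float = DEFAULT_SHELL_FRACTION,
) -> float:
    """Fraction of marker-positive positions in the outer radial shell.

    A position counts as peripheral when its distance from the centroid is
    at least (1 − shell_fraction)·radius. Used for proliferation markers
    (Ki67) that localize next to the basement membrane.
    """
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    if not 0 < shell_fraction < 1:
        raise ValueError("shell_fraction must lie in (0, 1)")
    pos = np.atleast_2d(np.asarray(marker_positions, dtype=float))
    if pos.size == 0:
        raise IndeterminatePeripheralError("no marker-positive positions")
    d = np.linalg.norm(pos - np.asarray(centroid, dtype=float), axis=1)
    return float(np.mean(d >= (1.0 - shell_fraction) * radius_um))
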