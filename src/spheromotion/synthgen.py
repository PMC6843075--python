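"""Synthetic scene generation with machine-readable ground truth.

Every generator emulates one class of observation used in the hydrogel
microstructure experiments — rotating spheroid time-lapse movies, thin
fluorescent basement-membrane shells, two-channel live/dead volumes and
major/minor-axis "popping" series — and returns the scene together with a
:class:`SyntheticTruth` record holding the exact parameters that produced
it. The analysis modules are validated by recovering those truths.

Geometry convention: physical coordinates use x to the right and y up, so
a positive angular velocity is a counterclockwise rotation in that frame.
Array row index increases downward; the renderers convert internally.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import optimize
from scipy.stats import truncnorm

from .io import TimeLapseMovie, ZStack

# Rendering scale: signal amplitude 1.0 maps to this many camera counts.
_COUNTS_PER_UNIT = 10_000.0
_UINT16_MAX = 65_535


@dataclass
class SceneConfig:
    """Acquisition parameters shared by the synthetic scenes.

    Defaults follow the experimental protocol (5-min frame interval, 15-h
    recordings) and a typical confocal sampling of 0.5 um per pixel.
    """

    pixel_size_um: float = 0.5
    frame_interval_min: float = 5.0
    duration_h: float = 15.0
    noise_sigma: float = 0.02
    drift_um_per_h: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_h * 60.0 / self.frame_interval_min)) + 1


@dataclass
class SpheroidSpec:
    """A rigidly rotating, blob-textured multicellular spheroid.

    ``omega_rev_h`` is signed: positive rotates counterclockwise (x right,
    y up). ``cell_jitter_um`` adds independent per-cell motion on top of
    the rigid rotation, emulating uncoordinated structures.
    """

    diameter_um: float = 34.0
    n_cells: int = 8
    omega_rev_h: float = 0.28
    boundary_roughness: float = 0.06
    cell_jitter_um: float = 0.0

    def __post_init__(self) -> None:
        if not 10.0 < self.diameter_um < 120.0:
            raise ValueError("diameter_um must lie in (10, 120)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.boundary_roughness < 0.5:
            raise ValueError("boundary_roughness must lie in [0, 0.5)")
        if self.cell_jitter_um < 0:
            raise ValueError("cell_jitter_um must be >= 0")


@dataclass
class ShellSpec:
    """A thin marker shell over a spherical structure surface.

    ``coverage_fraction`` is the fraction of the sphere's solid angle that
    is marker-positive, split over ``patch_count`` equal spherical caps
    (1 = one continuous cap; a full shell when the fraction is 1).
    """

    radius_um: float = 15.0
    shell_thickness_um: float = 2.0
    coverage_fraction: float = 1.0
    patch_count: int = 1
    marker_intensity: float = 1.0
    background_intensity: float = 0.02

    def __post_init__(self) -> None:
        if self.radius_um <= 0 or self.shell_thickness_um <= 0:
            raise ValueError("radius and shell thickness must be > 0")
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must lie in [0, 1]")
        if self.patch_count < 1:
            raise ValueError("patch_count must be >= 1")
        if self.marker_intensity <= self.background_intensity:
            raise ValueError("marker_intensity must exceed background_intensity")


@dataclass
class LiveDeadSpec:
    """A two-channel live/dead volume with known cluster structure.

    ``cluster_size_distribution`` maps cells-per-cluster to the probability
    that a *cluster* has that size; dead cells are always placed as single
    cells (they neither divide nor join clusters).
    """

    n_cells: int = 150
    dead_fraction: float = 0.257
    cluster_size_distribution: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.66, 5: 0.17, 6: 0.17}
    )
    min_separation_um: float = 25.0
    cell_radius_um: float = 5.0
    box_side_um: float | None = None  # None: sized automatically from n_cells

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must lie in [0, 1]")
        total = float(sum(self.cluster_size_distribution.values()))
        if not math.isclose(total, 1.0, abs_tol=1e-8):
            raise ValueError("cluster size probabilities must sum to 1")
        if any(k < 1 for k in self.cluster_size_distribution):
            raise ValueError("cluster sizes must be >= 1")
        if self.min_separation_um <= 0 or self.cell_radius_um <= 0:
            raise ValueError("separations and radii must be > 0")


@dataclass
class PopSpec:
    """Parameters of a popping-cycle axis series.

    Each cycle is a slow contractile phase followed by a fast tensile ramp
    ("pop") that multiplies the structure volume by 1 + expansion/100.
    Per-cycle durations and expansions are drawn around the stated means
    with the given spreads (set the spreads to 0 for exact cycles).
    """

    n_cycles: int = 3
    cycle_duration_h: float = 0.67
    expansion_percent: float = 42.8
    baseline_diameter_um: float = 100.0
    sampling_interval_min: float = 5.0
    duration_sd_h: float = 0.0
    expansion_sd_percent: float = 0.0
    contraction_rate_per_h: float = 0.12
    aspect_ratio: float = 1.15
    axis_noise_rel: float = 0.002

    def __post_init__(self) -> None:
        for name in (
            "n_cycles",
            "cycle_duration_h",
            "expansion_percent",
            "baseline_diameter_um",
            "sampling_interval_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.expansion_percent >= 200:
            raise ValueError("expansion_percent must be < 200")
        if self.aspect_ratio < 1.0:
            raise ValueError("aspect_ratio must be >= 1 (major over minor)")


@dataclass
class SyntheticTruth:
    """Ground truth paired with one generated scene.

    ``true_values`` keys match the names the analysis pipeline reports
    (omega_rev_h, coverage_fraction, viable_fraction, clustered_fraction,
    cycle_durations_h, expansion_percents, peripheral_fraction, ...).
    ``detail`` carries generator-internal arrays (placed centroids, applied
    angles) used by ground-truth-consistency checks.
    """

    scene_id: str
    true_values: dict
    detail: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rotating movies
# ---------------------------------------------------------------------------


def _rotation_matrix(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])


def make_rotating_movie(
    scene: SceneConfig, sph: SpheroidSpec
) -> tuple[TimeLapseMovie, SyntheticTruth]:
    """Render a textured spheroid rotating rigidly about its centroid.

    The spheroid is a soft-edged disk whose interior holds ``n_cells``
    Gaussian blobs at fixed intra-structure positions; rigid rotation is
    applied analytically to the blob positions and the boundary-roughness
    phase, so the per-interval rotation is exactly
    ``omega_rev_h * 360 * frame_interval_min / 60`` degrees. Linear drift,
    additive Gaussian noise and a ±5% per-frame intensity jitter are added
    on top.
    """
    px = scene.pixel_size_um
    radius = sph.diameter_um / 2.0
    if sph.diameter_um < 4.0 * px:
        raise ValueError(
            f"spheroid diameter {sph.diameter_um} um spans fewer than 4 pixels "
            f"at {px} um/pixel; reduce pixel size"
        )
    rng = np.random.default_rng(scene.seed)
    n_frames = scene.n_frames
    if n_frames < 2:
        raise ValueError("scene must contain at least 2 frames")

    drift_total = scene.drift_um_per_h * scene.duration_h
    half_um = radius * (1 + sph.boundary_roughness) + drift_total / 2.0 + 6.0
    half_px = int(math.ceil(half_um / px))
    side = 2 * half_px + 1

    # fixed intra-structure texture: cell blobs kept inside the body edge
    # so the outline stays smooth (compact multicellular structures)
    blob_sigma = rng.uniform(2.0, 3.0, sph.n_cells)
    rr_max = np.maximum(radius - 2.2 * blob_sigma, 0.2 * radius)
    rr = rr_max * np.sqrt(rng.uniform(0.05, 1.0, sph.n_cells))
    th = rng.uniform(0, 2 * np.pi, sph.n_cells)
    blob_xy = np.stack([rr * np.cos(th), rr * np.sin(th)], axis=1)  # (n, 2) um
    blob_amp = rng.uniform(0.35, 0.6, sph.n_cells)
    rough_phase = rng.uniform(0, 2 * np.pi)
    rough_k = int(rng.integers(3, 6))

    drift_dir = rng.uniform(0, 2 * np.pi)
    drift_vec = np.array([np.cos(drift_dir), np.sin(drift_dir)])

    # physical coordinate grids (x right, y up), origin at image center
    idx = (np.arange(side) - half_px) * px
    xg, yg = np.meshgrid(idx, -idx, indexing="xy")  # row 0 is top => y flips

    dt_h = scene.frame_interval_min / 60.0
    step_deg = sph.omega_rev_h * 360.0 * dt_h
    frames = np.empty((n_frames, side, side), dtype=np.uint16)
    edge_w = max(px, 0.75)

    for t in range(n_frames):
        angle = step_deg * t
        center = drift_vec * (scene.drift_um_per_h * dt_h * t - drift_total / 2.0)
        dx = xg - center[0]
        dy = yg - center[1]
        r = np.hypot(dx, dy)
        phi = np.arctan2(dy, dx)
        # boundary roughness co-rotates with the structure
        r_edge = radius * (
            1.0
            + sph.boundary_roughness
            * np.cos(rough_k * (phi - math.radians(angle)) + rough_phase)
        )
        body = 0.6 / (1.0 + np.exp((r - r_edge) / edge_w))
        rot = _rotation_matrix(angle)
        pos = blob_xy @ rot.T
        if sph.cell_jitter_um > 0:
            pos = pos + rng.normal(0.0, sph.cell_jitter_um, pos.shape)
        img = body
        for (bx, by), s, a in zip(pos, blob_sigma, blob_amp):
            d2 = (dx - bx) ** 2 + (dy - by) ** 2
            img = img + a * np.exp(-d2 / (2 * s * s))
        img = img * (1.0 + rng.uniform(-0.05, 0.05))
        if scene.noise_sigma > 0:
            img = img + rng.normal(0.0, scene.noise_sigma, img.shape)
        frames[t] = np.clip(img * _COUNTS_PER_UNIT, 0, _UINT16_MAX).astype(np.uint16)

    movie = TimeLapseMovie(frames, px, scene.frame_interval_min)
    truth = SyntheticTruth(
        scene_id=f"movie-seed{scene.seed}",
        true_values={
            "omega_rev_h": abs(sph.omega_rev_h),
            "direction": "CCW" if sph.omega_rev_h > 0 else ("CW" if sph.omega_rev_h < 0 else "none"),
            "step_deg": step_deg,
            "diameter_um": sph.diameter_um,
        },
        detail={"blob_xy_um": blob_xy, "drift_vec": drift_vec},
    )
    return movie, truth


# ---------------------------------------------------------------------------
# marker shells
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistributed unit vectors."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def make_shell_stack(
    scene: SceneConfig, shell: ShellSpec
) -> tuple[ZStack, SyntheticTruth]:
    """Render a two-channel volume: structure body and thin marker shell.

    Channel 0 holds the structure body (a filled sphere), channel 1 the
    marker: voxels within ±thickness/2 of the sphere surface whose
    direction falls inside one of ``patch_count`` equal spherical caps that
    jointly cover ``coverage_fraction`` of the solid angle. Cap centers are
    spread quasi-uniformly (randomly oriented), so caps stay disjoint for
    the coverage/patch combinations of interest and the marker's true
    solid-angle fraction equals the configured coverage fraction.
    """
    voxel = (2 * scene.pixel_size_um, scene.pixel_size_um, scene.pixel_size_um)
    if shell.shell_thickness_um < min(voxel):
        raise ValueError(
            "shell thinner than one voxel; reduce the voxel size "
            f"(thickness {shell.shell_thickness_um} um vs voxel {min(voxel)} um)"
        )
    rng = np.random.default_rng(scene.seed)
    r = shell.radius_um
    t = shell.shell_thickness_um
    margin = t + 2.0
    half = r + margin
    shape = tuple(int(math.ceil(2 * half / v)) + 1 for v in voxel)
    zc, yc, xc = ((n - 1) / 2.0 for n in shape)
    zz = (np.arange(shape[0]) - zc) * voxel[0]
    yy = (np.arange(shape[1]) - yc) * voxel[1]
    xx = (np.arange(shape[2]) - xc) * voxel[2]
    dz, dy, dx = np.meshgrid(zz, yy, xx, indexing="ij")
    dist = np.sqrt(dz * dz + dy * dy + dx * dx)

    body = np.where(dist <= r, 0.5, shell.background_intensity)
    marker = np.full(shape, shell.background_intensity)

    in_shell = np.abs(dist - r) <= t / 2.0
    f = shell.coverage_fraction
    if f > 0:
        if f >= 1.0:
            covered = in_shell
        else:
            # equal caps: per-cap solid angle 4*pi*f/p => cos half-angle
            cos_cap = 1.0 - 2.0 * f / shell.patch_count
            centers = _fibonacci_sphere(shell.patch_count)
            # random global orientation, seeded
            q = rng.normal(size=(3, 3))
            qr, _ = np.linalg.qr(q)
            centers = centers @ qr.T
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = np.stack([dz, dy, dx], axis=0) / np.maximum(dist, 1e-9)
            cosmax = np.full(shape, -1.0)
            for c in centers:
                cosang = c[0] * unit[0] + c[1] * unit[1] + c[2] * unit[2]
                np.maximum(cosmax, cosang, out=cosmax)
            covered = in_shell & (cosmax >= cos_cap)
        marker[covered] = shell.marker_intensity
    if scene.noise_sigma > 0:
        body = body + rng.normal(0, scene.noise_sigma * 0.5, shape)
        marker = marker + rng.normal(0, scene.noise_sigma * shell.marker_intensity, shape)

    data = np.clip(
        np.stack([body, marker]) * _COUNTS_PER_UNIT, 0, _UINT16_MAX
    ).astype(np.uint16)
    stack = ZStack(data, voxel)
    truth = SyntheticTruth(
        scene_id=f"shell-seed{scene.seed}",
        true_values={
            "coverage_fraction": f,
            "radius_um": r,
            "shell_thickness_um": t,
            "patch_count": shell.patch_count,
            "marker_voxels": int(np.count_nonzero(covered)) if f > 0 else 0,
            "shell_voxels": int(np.count_nonzero(in_shell)),
        },
    )
    return stack, truth


# ---------------------------------------------------------------------------
# live/dead volumes
# ---------------------------------------------------------------------------


def _allocate_clusters(n_live: int, dist: Mapping[int, float]) -> list[int]:
    """Deterministically allocate live cells to cluster sizes.

    The distribution gives per-cluster size probabilities; the allocation
    matches the implied cell-level weights k*p_k by largest remainder, then
    reconciles the total with extra/removed singles so exactly ``n_live``
    cells are placed.
    """
    sizes = sorted(dist)
    weights = np.array([k * dist[k] for k in sizes], dtype=float)
    weights /= weights.sum()
    # target number of clusters of each size
    raw = n_live * weights / np.array(sizes, dtype=float)
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(rem)[::-1]:
        if (counts * np.array(sizes)).sum() + sizes[i] <= n_live:
            counts[i] += 1
    leftover = n_live - int((counts * np.array(sizes)).sum())
    out: list[int] = []
    for k, c in zip(sizes, counts):
        out.extend([k] * int(c))
    out.extend([1] * leftover)  # remainder cells become singles
    return out


def make_livedead_scene(
    scene: SceneConfig, spec: LiveDeadSpec
) -> tuple[ZStack, SyntheticTruth]:
    """Render a two-channel live/dead volume with known composition.

    Channel 0 marks viable cells (calcein-like), channel 1 dead cells
    (ethidium-like). Dead cells are placed only as single cells; viable
    cells are grouped into clusters whose sizes follow the configured
    distribution (deterministic largest-remainder allocation, so the
    cell-level clustered fraction sits at the distribution's operating
    point for every seed). Structures are packed with at least
    ``min_separation_um`` between structure centers.
    """
    rng = np.random.default_rng(scene.seed)
    n_dead = int(round(spec.n_cells * spec.dead_fraction))
    n_live = spec.n_cells - n_dead
    if n_live < 0:
        raise ValueError("dead_fraction inconsistent with n_cells")
    cluster_sizes = _allocate_clusters(n_live, spec.cluster_size_distribution) if n_live else []
    structures = [("live", k) for k in cluster_sizes] + [("dead", 1)] * n_dead

    n_struct = len(structures)
    sep = spec.min_separation_um
    if spec.box_side_um is not None:
        side = spec.box_side_um
    else:
        side = max(1.8 * sep * n_struct ** (1 / 3.0), 3 * sep)
    depth = side / 2.0

    centers = []
    attempts = 0
    while len(centers) < n_struct:
        cand = np.array(
            [
                rng.uniform(sep / 2, depth - sep / 2),
                rng.uniform(sep / 2, side - sep / 2),
                rng.uniform(sep / 2, side - sep / 2),
            ]
        )
        if all(np.linalg.norm(cand - c) >= sep for c in centers):
            centers.append(cand)
        attempts += 1
        if attempts > 200 * n_struct + 1000:
            raise ValueError(
                f"packing failure: cannot place {n_struct} structures at "
                f"min separation {sep} um"
            )
    order = rng.permutation(n_struct)

    cell_pos = []  # (z, y, x) um
    cell_state = []  # 'live' | 'dead'
    cell_struct = []  # structure index
    shell_r = 1.6 * spec.cell_radius_um
    for si, oi in enumerate(order):
        state, k = structures[oi]
        c = centers[si]
        if k == 1:
            pts = c[None, :]
        else:
            unit = _fibonacci_sphere(k)
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            pts = c[None, :] + (unit @ q.T) * shell_r
        for p in pts:
            cell_pos.append(p)
            cell_state.append(state)
            cell_struct.append(si)
    cell_pos = np.array(cell_pos)
    cell_state = np.array(cell_state)

    voxel = (2.0, 1.0, 1.0)  # um; live/dead screens tolerate coarser sampling
    shape = (
        int(math.ceil(depth / voxel[0])) + 1,
        int(math.ceil(side / voxel[1])) + 1,
        int(math.ceil(side / voxel[2])) + 1,
    )
    vols = np.full((2,) + shape, 0.02, dtype=np.float64)
    sigma = spec.cell_radius_um / 1.7
    zz = np.arange(shape[0]) * voxel[0]
    yy = np.arange(shape[1]) * voxel[1]
    xx = np.arange(shape[2]) * voxel[2]
    for p, state in zip(cell_pos, cell_state):
        ch = 0 if state == "live" else 1
        iz = np.searchsorted(zz, p[0])
        iy = np.searchsorted(yy, p[1])
        ix = np.searchsorted(xx, p[2])
        w = int(math.ceil(3 * sigma / min(voxel)))
        sl = (
            slice(max(iz - w // 2, 0), iz + w // 2 + 1),
            slice(max(iy - w, 0), iy + w + 1),
            slice(max(ix - w, 0), ix + w + 1),
        )
        dz = zz[sl[0]] - p[0]
        dy = yy[sl[1]] - p[1]
        dx = xx[sl[2]] - p[2]
        d2 = (
            dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2
        )
        vols[ch][sl] += np.exp(-d2 / (2 * sigma * sigma))
    if scene.noise_sigma > 0:
        vols += rng.normal(0, scene.noise_sigma, vols.shape)

    data = np.clip(vols * _COUNTS_PER_UNIT, 0, _UINT16_MAX).astype(np.uint16)
    stack = ZStack(data, voxel)

    live_mask = cell_state == "live"
    struct_ids = np.array(cell_struct)
    clustered = 0
    for si in np.unique(struct_ids[live_mask]):
        members = np.count_nonzero((struct_ids == si) & live_mask)
        if members >= 2:
            clustered += members
    truth = SyntheticTruth(
        scene_id=f"livedead-seed{scene.seed}",
        true_values={
            "n_cells": spec.n_cells,
            "n_dead": n_dead,
            "n_live": n_live,
            "viable_fraction": n_live / spec.n_cells,
            "clustered_fraction": clustered / n_live if n_live else 0.0,
        },
        detail={
            "cell_pos_um": cell_pos,
            "cell_state": cell_state,
            "cell_struct": struct_ids,
            "cell_radius_um": spec.cell_radius_um,
        },
    )
    return stack, truth


# ---------------------------------------------------------------------------
# popping axis series
# ---------------------------------------------------------------------------


def make_popping_series(spec: PopSpec, seed: int = 0):
    """Generate a major/minor-axis series with known popping cycles.

    Returns ``(series_df, truth)`` where the series is a DataFrame with
    columns ``time_h, major_um, minor_um``. Each cycle holds a slow
    contractile drift followed by a two-sample tensile ramp; plateau levels
    are solved so that the median volume of the contractile phase after a
    pop exceeds the one before it by exactly the cycle's expansion percent,
    which is also what the truth records.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    dt = spec.sampling_interval_min / 60.0
    if dt >= spec.cycle_duration_h:
        raise ValueError(
            "sampling interval >= cycle duration: cycles unresolvable at "
            f"{spec.sampling_interval_min} min sampling"
        )
    ramp_h = 2 * dt
    min_T = max(ramp_h + 2 * dt, 0.25)
    durations = np.maximum(
        rng.normal(spec.cycle_duration_h, spec.duration_sd_h, spec.n_cycles), min_T
    )
    expansions = np.maximum(
        rng.normal(spec.expansion_percent, spec.expansion_sd_percent, spec.n_cycles),
        5.0,
    )
    tail_h = 0.5
    c = spec.contraction_rate_per_h

    v0 = math.pi / 6.0 * spec.baseline_diameter_um**3
    # contractile phase lengths (pop ramp excluded)
    tc = durations - ramp_h
    # solve plateau levels so median ratios equal the target expansions
    levels = [v0]
    medians = []
    for i in range(spec.n_cycles):
        med_i = levels[i] * (1 - c * tc[i] / 2.0)
        medians.append(med_i)
        tc_next = tc[i + 1] if i + 1 < spec.n_cycles else tail_h
        target_med = med_i * (1 + expansions[i] / 100.0)
        levels.append(target_med / (1 - c * tc_next / 2.0))

    times = [0.0]
    vols = [levels[0]]
    t = 0.0
    pop_times = []
    boundaries = [0.0]
    for i in range(spec.n_cycles):
        n_c = max(int(round(tc[i] / dt)), 2)
        start_v = levels[i]
        for j in range(1, n_c + 1):
            t += dt
            times.append(t)
            vols.append(start_v * (1 - c * (j * dt)))
        pop_times.append(t)
        v_pre = vols[-1]
        for j in range(1, 3):  # two-sample tensile ramp
            t += dt
            times.append(t)
            vols.append(v_pre + (levels[i + 1] - v_pre) * j / 2.0)
        boundaries.append(t)
    n_tail = int(round(tail_h / dt))
    start_v = levels[-1]
    for j in range(1, n_tail + 1):
        t += dt
        times.append(t)
        vols.append(start_v * (1 - c * (j * dt)))

    vols = np.array(vols)
    times = np.array(times)
    a = spec.aspect_ratio
    minor = (6.0 * vols / (math.pi * a)) ** (1.0 / 3.0)
    major = a * minor
    if spec.axis_noise_rel > 0:
        major = major * (1 + rng.normal(0, spec.axis_noise_rel, major.shape))
        minor = minor * (1 + rng.normal(0, spec.axis_noise_rel, minor.shape))
    df = pd.DataFrame({"time_h": times, "major_um": major, "minor_um": minor})

    cycle_durations = np.diff(boundaries)
    truth = SyntheticTruth(
        scene_id=f"pops-seed{seed}",
        true_values={
            "n_cycles": spec.n_cycles,
            "cycle_durations_h": list(cycle_durations),
            "expansion_percents": list(expansions),
            "volume_ratio_terminal": float(
                (medians[-1] * (1 + expansions[-1] / 100.0)) / medians[0]
                if spec.n_cycles == 1
                else np.nan
            ),
            "pop_times_h": list(np.array(pop_times)),
        },
        detail={"plateau_levels_um3": levels, "medians_um3": medians},
    )
    return df, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def calibrate_truncnorm_mu(target_mean: float, sd: float) -> float:
    """Pre-truncation location whose zero-truncated normal has the target mean.

    Benchmark cohorts draw structure-level angular speeds from a normal law
    truncated at zero; truncation shifts the mean upward, so the location
    parameter is solved (Brent) to keep the truncated mean at the printed
    group operating point.
    """
    if sd == 0:
        return target_mean

    def f(mu):
        return truncnorm.mean((0 - mu) / sd, np.inf, loc=mu, scale=sd) - target_mean

    lo = target_mean - 6 * sd
    hi = target_mean + sd
    return float(optimize.brentq(f, lo, hi))


def sample_cohort_omegas(
    n: int, omega_mean: float, omega_sd: float, rng, sampling: str = "stratified"
) -> np.ndarray:
    """Draw n non-negative angular speeds from the truncated normal law.

    ``stratified`` (default) takes the quantile midpoints of the truncated
    law in a random order, pinning the cohort's empirical mean at the
    calibrated operating point; ``iid`` draws independently.
    """
    if omega_sd == 0:
        return np.full(n, omega_mean)
    mu = calibrate_truncnorm_mu(omega_mean, omega_sd)
    a = (0 - mu) / omega_sd
    if sampling == "stratified":
        q = (np.arange(n) + 0.5) / n
        vals = truncnorm.ppf(q, a, np.inf, loc=mu, scale=omega_sd)
        return rng.permutation(vals)
    if sampling == "iid":
        return truncnorm.rvs(a, np.inf, loc=mu, scale=omega_sd, size=n, random_state=rng)
    raise ValueError(f"unknown sampling mode: {sampling}")


def make_cohort(
    group_name: str,
    n_structures: int,
    omega_mean: float,
    omega_sd: float,
    scene: SceneConfig,
    seed: int,
    *,
    diameter_mean_um: float = 34.0,
    diameter_sd_um: float = 5.0,
    sampling: str = "stratified",
):
    """Generate a cohort of rotating movies with per-structure truths.

    Structure-level true speeds come from a normal law truncated at zero
    (see :func:`sample_cohort_omegas`); rotation direction (CW/CCW) is
    assigned at random per structure, as both occur within the same gel.
    Returns a list of ``(TimeLapseMovie, SyntheticTruth)`` pairs.
    """
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    if omega_mean < 0:
        raise ValueError("omega_mean must be >= 0")
    name_tag = zlib.crc32(group_name.encode()) & 0xFFFF
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, name_tag])
    rng = np.random.default_rng(ss)
    omegas = sample_cohort_omegas(n_structures, omega_mean, omega_sd, rng, sampling)
    signs = rng.choice([-1.0, 1.0], n_structures)
    diam = np.clip(
        rng.normal(diameter_mean_um, diameter_sd_um, n_structures), 20.0, 52.0
    )
    child_seeds = ss.spawn(n_structures)
    out = []
    for i in range(n_structures):
        sc = replace(scene, seed=int(child_seeds[i].generate_state(1)[0] & 0x7FFFFFFF))
        sph = SpheroidSpec(
            diameter_um=float(diam[i]),
            omega_rev_h=float(signs[i] * omegas[i]),
        )
        movie, truth = make_rotating_movie(sc, sph)
        truth.scene_id = f"{group_name}-{i:03d}"
        truth.true_values["group"] = group_name
        out.append((movie, truth))
    return out
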