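"""Live/dead classification, cluster assignment and cluster-size histograms.

Cells are detected as blobs in a two-channel (calcein-like / ethidium-like)
volume, classified by dominant channel with a 2:1 intensity-ratio margin
(ambiguous cells are reported as unclassified rather than forced), and
viable cells are grouped into structures by single-linkage at a contact
distance. Cluster-size histograms use the half-open convention: bin k
counts structures whose cell count lies in [k, k+1), i.e. including k but
excluding k+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage import feature, filters

from .io import ZStack

DEFAULT_CELL_RADIUS_UM = 5.0
DEFAULT_SURFACE_GAP_UM = 2.0  # contact: centroid distance <= sum of radii + gap
DEFAULT_RATIO_MARGIN = 2.0


def default_contact_distance(cell_radius_um: float = DEFAULT_CELL_RADIUS_UM) -> float:
    return 2.0 * cell_radius_um + DEFAULT_SURFACE_GAP_UM


@dataclass
class ViabilityResult:
    """Counts and fractions for one live/dead volume."""

    n_live: int
    n_dead: int
    n_unclassified: int = 0
    clustered_fraction: float | None = None

    @property
    def viable_percent(self) -> float:
        total = self.n_live + self.n_dead
        if total == 0:
            raise ValueError("no classified cells")
        return 100.0 * self.n_live / total

    @property
    def single_fraction(self) -> float | None:
        if self.clustered_fraction is None:
            return None
        return 1.0 - self.clustered_fraction


@dataclass
class ClusterHistogram:
    """Half-open cluster-size histogram: bin k covers [k, k+1)."""

    bins: dict
    by_diameter: pd.DataFrame | None = None

    @property
    def n_structures(self) -> int:
        return int(sum(self.bins.values()))


def detect_cells(
    stack: ZStack,
    *,
    cell_radius_um: float = DEFAULT_CELL_RADIUS_UM,
    roi: tuple | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect cell centroids (um) and per-channel peak intensities.

    Peaks of the smoothed channel sum are cell candidates; ``roi`` is an
    optional ((z0, z1), (y0, y1), (x0, x1)) box in um restricting the
    evaluation to a region of interest of known volume.
    """
    vz, vy, vx = stack.voxel_size_um
    combined = stack.data.astype(float).sum(axis=0)
    sigma = tuple(cell_radius_um / 2.5 / s for s in (vz, vy, vx))
    smooth = ndimage.gaussian_filter(combined, sigma)
    if np.ptp(smooth) == 0:
        raise ValueError("no cells detected: empty volume")
    thr = filters.threshold_otsu(smooth)
    half = tuple(max(int(round(0.9 * cell_radius_um / s)), 1) for s in (vz, vy, vx))
    footprint = np.ones(tuple(2 * h + 1 for h in half), dtype=bool)
    peaks = feature.peak_local_max(
        smooth, footprint=footprint, threshold_abs=thr, exclude_border=False
    )
    if peaks.size == 0:
        raise ValueError("no cells detected")
    centroids = peaks * np.array([vz, vy, vx])
    if roi is not None:
        keep = np.ones(len(centroids), dtype=bool)
        for ax, (lo, hi) in enumerate(roi):
            keep &= (centroids[:, ax] >= lo) & (centroids[:, ax] < hi)
        peaks, centroids = peaks[keep], centroids[keep]
        if len(centroids) == 0:
            raise ValueError("no cells detected in ROI")
    # per-cell channel intensity: local mean around each peak
    rad_vox = tuple(max(int(round(cell_radius_um / 2 / s)), 1) for s in (vz, vy, vx))
    intensities = np.zeros((len(peaks), stack.n_channels))
    for ci in range(stack.n_channels):
        chan = stack.data[ci].astype(float)
        for pi, p in enumerate(peaks):
            sl = tuple(
                slice(max(p[a] - rad_vox[a], 0), p[a] + rad_vox[a] + 1)
                for a in range(3)
            )
            intensities[pi, ci] = chan[sl].mean()
    return centroids, intensities


def classify_live_dead(
    stack: ZStack,
    *,
    live_channel: int = 0,
    dead_channel: int = 1,
    cell_radius_um: float = DEFAULT_CELL_RADIUS_UM,
    ratio_margin: float = DEFAULT_RATIO_MARGIN,
    roi: tuple | None = None,
) -> tuple[ViabilityResult, np.ndarray, np.ndarray]:
    """Classify detected cells as live, dead or unclassified.

    Returns ``(result, centroids_um, states)`` where states holds
    'live' / 'dead' / 'unclassified' per cell. A cell is live when its
    live-channel intensity is at least ``ratio_margin`` times the dead
    channel's (net of the volume background), and vice versa.
    """
    if stack.n_channels <= max(live_channel, dead_channel):
        raise ValueError("both live and dead channels must be present")
    centroids, intens = detect_cells(stack, cell_radius_um=cell_radius_um, roi=roi)
    bg = np.array(
        [np.median(stack.data[c]) for c in range(stack.n_channels)], dtype=float
    )
    net = np.clip(intens - bg, 0, None)
    live_i = net[:, live_channel]
    dead_i = net[:, dead_channel]
    states = np.full(len(centroids), "unclassified", dtype=object)
    states[live_i >= ratio_margin * dead_i] = "live"
    states[dead_i >= ratio_margin * live_i] = "dead"
    both_zero = (live_i == 0) & (dead_i == 0)
    states[both_zero] = "unclassified"
    result = ViabilityResult(
        n_live=int(np.count_nonzero(states == "live")),
        n_dead=int(np.count_nonzero(states == "dead")),
        n_unclassified=int(np.count_nonzero(states == "unclassified")),
    )
    return result, centroids, states


def assign_clusters(cell_centroids: np.ndarray, contact_distance_um: float) -> np.ndarray:
    """Single-linkage cluster labels at the contact distance.

    Two cells belong to the same structure when a chain of pairwise
    contacts (centroid distance ≤ contact distance) joins them.
    """
    pts = np.atleast_2d(np.asarray(cell_centroids, dtype=float))
    n = len(pts)
    if n == 0:
        raise ValueError("at least one centroid is required")
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=contact_distance_um, output_type="ndarray")
    if len(pairs) == 0:
        return np.arange(n)
    data = np.ones(len(pairs))
    adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def cluster_histogram(
    cluster_sizes,
    diameters=None,
    diameter_bin_um: float = 10.0,
) -> ClusterHistogram:
    """Half-open [k, k+1) histogram of cells-per-structure.

    ``cluster_sizes`` may be fractional (e.g. mean cells per structure);
    value 5.5 falls in bin 5. ``diameters`` (one per structure, um)
    optionally adds a size-vs-diameter cross-tab.
    """
    sizes = np.asarray(list(cluster_sizes), dtype=float)
    bins: dict[int, int] = {}
    for s in sizes:
        k = int(np.floor(s))
        bins[k] = bins.get(k, 0) + 1
    by_diameter = None
    if diameters is not None and len(sizes):
        d = np.asarray(list(diameters), dtype=float)
        df = pd.DataFrame(
            {
                "size_bin": np.floor(sizes).astype(int),
                "diameter_bin_um": (np.floor(d / diameter_bin_um) * diameter_bin_um),
            }
        )
        by_diameter = df.value_counts().unstack(fill_value=0)
    return ClusterHistogram(bins=dict(sorted(bins.items())), by_diameter=by_diameter)


def viability_report(
    stack: ZStack,
    *,
    cell_radius_um: float = DEFAULT_CELL_RADIUS_UM,
    contact_distance_um: float | None = None,
    roi: tuple | None = None,
) -> tuple[ViabilityResult, ClusterHistogram]:
    """Full live/dead + clustering analysis of a two-channel volume.

    Viable cells are clustered at the contact distance (default: two cell
    radii plus a 2 um surface gap); the clustered fraction is the share of
    viable cells sitting in structures of two or more cells.
    """
    if contact_distance_um is None:
        contact_distance_um = default_contact_distance(cell_radius_um)
    result, centroids, states = classify_live_dead(
        stack, cell_radius_um=cell_radius_um, roi=roi
    )
    live_pts = centroids[states == "live"]
    if len(live_pts) == 0:
        result.clustered_fraction = 0.0
        return result, ClusterHistogram(bins={})
    labels = assign_clusters(live_pts, contact_distance_um)
    _, counts = np.unique(labels, return_counts=True)
    clustered_cells = int(counts[counts >= 2].sum())
    result.clustered_fraction = clustered_cells / len(live_pts)
    hist = cluster_histogram(counts)
    return result, hist
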