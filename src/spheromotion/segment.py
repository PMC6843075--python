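"""Detection and measurement of microstructures in frames and volumes.

Masks come from an automatic global (Otsu) threshold with an optional
fixed override; measurements are reported in physical micrometres.
"Equivalent diameter" is defined from area (2D) or volume (3D), not from
axis means. Pixel indices are 0-based and the physical origin sits at the
image corner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, filters, measure

DEFAULT_MIN_DIAMETER_UM = 10.0  # debris below single-cell scale is excluded


@dataclass
class Microstructure:
    """One detected structure and its morphometrics (all lengths in um)."""

    label: int
    centroid_um: tuple
    equivalent_diameter_um: float
    major_axis_um: float
    minor_axis_um: float
    solidity: float
    n_cells: int | None = None
    centroid_px: tuple | None = None  # (row, col[, plane]) float, for registration
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.minor_axis_um > self.major_axis_um + 1e-9:
            raise ValueError("minor axis exceeds major axis")
        if not 0 < self.solidity <= 1 + 1e-9:
            raise ValueError("solidity must lie in (0, 1]")
        if self.equivalent_diameter_um <= 0:
            raise ValueError("equivalent diameter must be > 0")


def threshold_frame(frame: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Foreground mask by Otsu (default) or a fixed threshold."""
    frame = np.asarray(frame, dtype=float)
    if threshold is None:
        if np.ptp(frame) == 0:
            return np.zeros(frame.shape, dtype=bool)
        threshold = filters.threshold_otsu(frame)
    return frame > threshold


def segment_frame(
    frame: np.ndarray,
    pixel_size_um: float,
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
    threshold: float | None = None,
    smooth_sigma_px: float = 2.0,
) -> list[Microstructure]:
    """Detect structures in one 2D frame; one record per connected region.

    The frame is lightly Gaussian-smoothed (``smooth_sigma_px``, in
    pixels, so that physical measurements scale exactly with pixel size)
    before thresholding; intra-structure texture then does not fragment
    the mask. Structures whose equivalent diameter falls below
    ``min_diameter_um`` are discarded. An empty frame yields an empty
    list.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ValueError("pixel size is required and must be > 0")
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("segment_frame expects a 2D frame")
    if smooth_sigma_px > 0:
        frame = ndimage.gaussian_filter(frame.astype(float), smooth_sigma_px)
    mask = threshold_frame(frame, threshold)
    if not mask.any():
        return []
    mask = ndimage.binary_fill_holes(mask)
    labels = measure.label(mask)
    out: list[Microstructure] = []
    for rp in measure.regionprops(labels):
        eq_d = rp.equivalent_diameter_area * pixel_size_um
        if eq_d < min_diameter_um:
            continue
        r, c = rp.centroid
        out.append(
            Microstructure(
                label=rp.label,
                centroid_um=(c * pixel_size_um, r * pixel_size_um),
                equivalent_diameter_um=eq_d,
                major_axis_um=rp.axis_major_length * pixel_size_um,
                minor_axis_um=rp.axis_minor_length * pixel_size_um,
                solidity=rp.solidity,
                centroid_px=(r, c),
                mask=labels == rp.label,
            )
        )
    return out


def segment_volume(
    volume: np.ndarray,
    voxel_size_um: tuple,
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
    threshold: float | None = None,
) -> list[Microstructure]:
    """3D analogue of :func:`segment_frame` for confocal-like volumes.

    Equivalent diameter comes from the region volume; axes from the
    inertia-ellipsoid of the (isotropically resampled) region are not
    needed for the coverage workflow, so major/minor fall back to the
    equivalent diameter.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("segment_volume expects a 3D single-channel volume")
    vz, vy, vx = voxel_size_um
    mask = threshold_frame(volume, threshold)
    if not mask.any():
        return []
    mask = ndimage.binary_fill_holes(mask)
    labels = measure.label(mask)
    voxel_vol = vz * vy * vx
    out: list[Microstructure] = []
    for rp in measure.regionprops(labels):
        vol_um3 = rp.area * voxel_vol
        eq_d = (6.0 * vol_um3 / math.pi) ** (1.0 / 3.0)
        if eq_d < min_diameter_um:
            continue
        z, y, x = rp.centroid
        out.append(
            Microstructure(
                label=rp.label,
                centroid_um=(x * vx, y * vy, z * vz),
                equivalent_diameter_um=eq_d,
                major_axis_um=eq_d,
                minor_axis_um=eq_d,
                solidity=1.0,
                centroid_px=(z, y, x),
                mask=labels == rp.label,
            )
        )
    return out


def measure_axes(mask: np.ndarray, pixel_size_um: float) -> tuple[float, float]:
    """Best-fit ellipse major and minor axis lengths of a 2D mask, in um."""
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 5:
        raise ValueError("mask too small: ellipse axes undefined")
    rp = measure.regionprops(mask.astype(np.uint8))[0]
    return (
        rp.axis_major_length * pixel_size_um,
        rp.axis_minor_length * pixel_size_um,
    )


def count_cells(
    image: np.ndarray,
    nuclear_channel: int = 0,
    *,
    pixel_size_um,
    cell_radius_um: float = 4.0,
    mask: np.ndarray | None = None,
) -> int:
    """Count resolved nuclear blobs, declumping by local maxima.

    ``image`` is (C, ...) with the nuclear channel first-axis indexed;
    ``pixel_size_um`` is a scalar (2D) or (z, y, x) tuple (3D). Touching
    nuclei separated by at least one radius are split by maxima of the
    smoothed channel (watershed seeds).
    """
    image = np.asarray(image)
    if nuclear_channel >= image.shape[0] or nuclear_channel < 0:
        raise ValueError(
            f"nuclear channel {nuclear_channel} absent (found {image.shape[0]} channels)"
        )
    chan = image[nuclear_channel].astype(float)
    if np.isscalar(pixel_size_um):
        spacing = (float(pixel_size_um),) * chan.ndim
    else:
        spacing = tuple(float(v) for v in pixel_size_um)
    if mask is None:
        mask = threshold_frame(chan)
    if not np.any(mask):
        return 0
    sigma_vox = tuple(cell_radius_um / 2.5 / s for s in spacing)
    smooth = ndimage.gaussian_filter(chan, sigma_vox)
    # footprint narrower than the declumping limit (one radius separation)
    fp_half = tuple(max(int(round(0.5 * cell_radius_um / s)), 1) for s in spacing)
    footprint = np.ones(tuple(2 * h + 1 for h in fp_half), dtype=bool)
    thr = smooth[mask].mean() * 0.3
    peaks = feature.peak_local_max(
        smooth, footprint=footprint, labels=np.asarray(mask).astype(np.uint8),
        threshold_abs=thr, exclude_border=False,
    )
    return int(len(peaks))


def smoothness_ok(ms: Microstructure, solidity_min: float = 0.9) -> bool:
    """Inclusion gate: border regularity measured as convex solidity.

    Structures with irregular borders (below the solidity floor) are not
    quantifiable for rotation or coordination and are excluded.
    """
    return bool(ms.solidity >= solidity_min)


def regions_table(structures: list[Microstructure]) -> pd.DataFrame:
    """Per-frame region table in the CSV layout the pipeline exchanges."""
    rows = []
    for ms in structures:
        rows.append(
            {
                "label": ms.label,
                "centroid_x_um": ms.centroid_um[0],
                "centroid_y_um": ms.centroid_um[1],
                "eq_diam_um": ms.equivalent_diameter_um,
                "major_um": ms.major_axis_um,
                "minor_um": ms.minor_axis_um,
                "solidity": ms.solidity,
                "n_cells": ms.n_cells,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "centroid_x_um",
            "centroid_y_um",
            "eq_diam_um",
            "major_um",
            "minor_um",
            "solidity",
            "n_cells",
        ],
    )
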