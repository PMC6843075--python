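"""Reading and writing of movies, stacks and axis series.

Movies and z-stacks travel as OME-TIFF with physical pixel/voxel sizes and
the frame interval in the OME metadata, so that downstream measurement never
needs side-channel information about scale. Axis series are plain CSV with
columns ``time_h, major_um, minor_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile


@dataclass
class TimeLapseMovie:
    """Ordered 2D intensity frames with physical calibration.

    frames: array of shape (T, H, W); pixel_size_um: edge length of one
    pixel (um); frame_interval_min: time between consecutive frames (min).
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_min: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("movie frames must have shape (T, H, W)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_h(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_min / 60.0


@dataclass
class ZStack:
    """Multi-channel 3D volume with anisotropic voxel calibration.

    data: array of shape (C, Z, Y, X); voxel_size_um: (z, y, x) edge
    lengths in um.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError("stack data must have shape (C, Z, Y, X)")
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size_um must be three positive lengths (z, y, x)")
        self.voxel_size_um = vs

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def channel(self, index: int) -> np.ndarray:
        if not 0 <= index < self.n_channels:
            raise ValueError(
                f"channel {index} absent: stack has {self.n_channels} channel(s)"
            )
        return self.data[index]


def write_movie(path, movie: TimeLapseMovie) -> None:
    """Write a movie as OME-TIFF with pixel size and time increment."""
    tifffile.imwrite(
        path,
        movie.frames,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "TYX",
            "PhysicalSizeX": movie.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": movie.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "TimeIncrement": movie.frame_interval_min,
            "TimeIncrementUnit": "min",
        },
    )


def read_movie(path) -> TimeLapseMovie:
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        px = tif.ome_metadata
        meta = tifffile.xml2dict(px)["OME"]["Image"]["Pixels"]
    return TimeLapseMovie(
        frames=frames,
        pixel_size_um=float(meta["PhysicalSizeX"]),
        frame_interval_min=float(meta["TimeIncrement"]),
    )


def write_stack(path, stack: ZStack) -> None:
    """Write a multi-channel volume as OME-TIFF with voxel sizes."""
    vz, vy, vx = stack.voxel_size_um
    tifffile.imwrite(
        path,
        stack.data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": vx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": vy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": vz,
            "PhysicalSizeZUnit": "µm",
        },
    )


def read_stack(path) -> ZStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tifffile.xml2dict(tif.ome_metadata)["OME"]["Image"]["Pixels"]
    return ZStack(
        data=data,
        voxel_size_um=(
            float(meta["PhysicalSizeZ"]),
            float(meta["PhysicalSizeY"]),
            float(meta["PhysicalSizeX"]),
        ),
    )


def write_axis_series(path, time_h, major_um, minor_um) -> None:
    pd.DataFrame(
        {"time_h": time_h, "major_um": major_um, "minor_um": minor_um}
    ).to_csv(path, index=False)


def read_axis_series(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"time_h", "major_um", "minor_um"} - set(df.columns)
    if missing:
        raise ValueError(f"axis series missing columns: {sorted(missing)}")
    return df
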