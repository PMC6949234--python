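"""Reconstruction-quality analysis: ROI statistics, line profiles,
contrast and ground-truth error.

These are the measurements used to judge a DBT reconstruction: the
mean/StdDev of a uniform background region (noise and uniformity), an
in-plane line profile through an object of interest (edge sharpness
and recovered value across iterations), the object-to-background
contrast, and — when a ground truth exists, i.e. for simulated data —
the relative L2 recovery error.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .projector import Volume

__all__ = ["ROI", "Profile", "roi_stats", "line_profile", "contrast", "recovery_error"]


@dataclass(frozen=True)
class ROI:
    """Rectangular in-plane region on one slice; ranges are half-open, 0-based."""

    slice_index: int
    row_range: tuple[int, int]  # along Y
    col_range: tuple[int, int]  # along X

    def __post_init__(self) -> None:
        if self.row_range[0] >= self.row_range[1] or self.col_range[0] >= self.col_range[1]:
            raise ValueError("ROI ranges must be non-empty")


@dataclass
class Profile:
    """Axis-aligned voxel segment on one slice, with sampled values."""

    slice_index: int
    start: tuple[int, int]  # (col, row) of first voxel
    end: tuple[int, int]  # (col, row) of last voxel, inclusive
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.start == self.end:
            raise ValueError("profile start and end must differ")
        if self.start[0] != self.end[0] and self.start[1] != self.end[1]:
            raise ValueError("profile must be axis-aligned")


def _check_roi(x: Volume, roi: ROI) -> None:
    nx, ny, nz = x.grid.shape
    if not 0 <= roi.slice_index < nz:
        raise ValueError(f"ROI slice {roi.slice_index} out of range [0, {nz})")
    if not (0 <= roi.row_range[0] and roi.row_range[1] <= ny):
        raise ValueError("ROI row range out of bounds")
    if not (0 <= roi.col_range[0] and roi.col_range[1] <= nx):
        raise ValueError("ROI col range out of bounds")


def roi_stats(x: Volume, roi: ROI) -> tuple[float, float]:
    """Mean and population standard deviation of the ROI voxels."""
    _check_roi(x, roi)
    block = x.values[
        roi.col_range[0] : roi.col_range[1],
        roi.row_range[0] : roi.row_range[1],
        roi.slice_index,
    ]
    return float(block.mean()), float(block.std())


def line_profile(x: Volume, profile: Profile) -> Profile:
    """Sample voxel values along an axis-aligned segment.

    Returns a new :class:`Profile` with ``values`` filled; values run
    from ``start`` to ``end`` inclusive, one per lattice point.
    """
    nx, ny, nz = x.grid.shape
    if not 0 <= profile.slice_index < nz:
        raise ValueError("profile slice out of range")
    (c0, r0), (c1, r1) = profile.start, profile.end
    for c, r in (profile.start, profile.end):
        if not (0 <= c < nx and 0 <= r < ny):
            raise ValueError("profile endpoint out of bounds")
    if c0 == c1:
        step = 1 if r1 >= r0 else -1
        vals = x.values[c0, r0 : r1 + step : step, profile.slice_index]
    else:
        step = 1 if c1 >= c0 else -1
        vals = x.values[c0 : c1 + step : step, r0, profile.slice_index]
    return Profile(profile.slice_index, profile.start, profile.end, np.array(vals))


def contrast(x: Volume, object_roi: ROI, background_roi: ROI) -> float:
    """Relative contrast ``(mean_obj - mean_bg) / mean_bg``.

    The package's operationalization of object-to-background contrast;
    positive for objects brighter than their surroundings.
    """
    mean_obj, _ = roi_stats(x, object_roi)
    mean_bg, _ = roi_stats(x, background_roi)
    if mean_bg == 0:
        raise ZeroDivisionError("background mean is zero; contrast undefined")
    return (mean_obj - mean_bg) / mean_bg


def recovery_error(x: Volume, truth: Volume) -> float:
    """Relative L2 error ``||x - truth|| / ||truth||`` against ground truth."""
    if x.grid.shape != truth.grid.shape:
        raise ValueError("volumes live on different grids")
    nt = float(np.linalg.norm(truth.values))
    if nt == 0:
        raise ZeroDivisionError("ground truth is zero; relative error undefined")
    return float(np.linalg.norm(x.values - truth.values) / nt)


def profile_to_csv(profiles: dict[str, Profile], path: str | Path) -> None:
    """Write named profiles side by side as CSV (full float precision)."""
    names = list(profiles)
    length = max(len(p.values) for p in profiles.values())
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index"] + names)
        for i in range(length):
            row = [i] + [
                repr(float(profiles[n].values[i])) if i < len(profiles[n].values) else ""
                for n in names
            ]
            writer.writerow(row)
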