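"""File I/O: HDF5 containers, raw float64 + JSON sidecar, TIFF export.

The HDF5 layout stores the numeric payload plus enough geometry/grid
metadata to rebuild the container; raw + sidecar is the
lowest-common-denominator exchange format (little-endian float64, C
order); per-slice TIFF stacks are for visual inspection only.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .geometry import ScanGeometry, VolumeGrid
from .projector import ProjectionStack, Volume

__all__ = [
    "save_projections_h5",
    "load_projections_h5",
    "save_volume_h5",
    "load_volume_h5",
    "save_raw",
    "load_raw",
    "save_volume_tiff",
    "save_projections_tiff",
    "write_iteration_log",
]


def write_iteration_log(state, path: str | Path) -> None:
    """CSV log of the solver trajectory: iteration, f, LS and TV parts,
    accepted backtracking factor eta, steplength alpha."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "f", "ls", "tv", "eta", "alpha"])
        writer.writerow([0, repr(state.f_history[0]), "", "", "", ""])
        for i in range(1, len(state.f_history)):
            writer.writerow(
                [
                    i,
                    repr(state.f_history[i]),
                    repr(state.ls_history[i - 1]),
                    repr(state.tv_history[i - 1]),
                    repr(state.eta_history[i - 1]),
                    repr(state.alpha_history[i - 1]),
                ]
            )


def save_projections_h5(stack: ProjectionStack, path: str | Path) -> None:
    g = stack.geometry
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=stack.values)
        f.create_dataset("angles_deg", data=np.asarray(g.angles_deg))
        f.attrs["source_detector_distance"] = g.source_detector_distance
        f.attrs["detector_pitch_x"] = g.detector_pitch_x
        f.attrs["detector_pitch_y"] = g.detector_pitch_y
        f.attrs["detector_origin"] = g.detector_origin
        f.attrs["arc_center"] = g.arc_center


def load_projections_h5(path: str | Path) -> ProjectionStack:
    with h5py.File(path, "r") as f:
        values = f["values"][()]
        geometry = ScanGeometry(
            source_detector_distance=float(f.attrs["source_detector_distance"]),
            angles_deg=tuple(f["angles_deg"][()]),
            detector_rows=values.shape[1],
            detector_cols=values.shape[2],
            detector_pitch_x=float(f.attrs["detector_pitch_x"]),
            detector_pitch_y=float(f.attrs["detector_pitch_y"]),
            detector_origin=tuple(f.attrs["detector_origin"]),
            arc_center=tuple(f.attrs["arc_center"]),
        )
    return ProjectionStack(values, geometry)


def save_volume_h5(volume: Volume, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=volume.values)
        f.attrs["voxel_size"] = volume.grid.voxel_size
        f.attrs["origin"] = volume.grid.origin


def load_volume_h5(path: str | Path) -> Volume:
    with h5py.File(path, "r") as f:
        values = f["values"][()]
        grid = VolumeGrid(
            shape=values.shape,
            voxel_size=tuple(f.attrs["voxel_size"]),
            origin=tuple(f.attrs["origin"]),
        )
    return Volume(values, grid)


def save_raw(array: np.ndarray, path: str | Path, meta: dict | None = None) -> None:
    """Raw little-endian float64 (C order) with a JSON sidecar."""
    path = Path(path)
    arr = np.ascontiguousarray(array, dtype="<f8")
    arr.tofile(path)
    sidecar = {"dtype": "<f8", "order": "C", "shape": list(arr.shape)}
    if meta:
        sidecar.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_raw(path: str | Path) -> np.ndarray:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    arr = np.fromfile(path, dtype=sidecar["dtype"])
    return arr.reshape(sidecar["shape"])


def save_volume_tiff(volume: Volume, path: str | Path) -> None:
    """Per-slice float32 TIFF stack (pages are XY slices, Z-ordered)."""
    # (N_x, N_y, N_z) -> pages (N_z, N_y, N_x) for conventional viewers
    pages = np.transpose(volume.values, (2, 1, 0)).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")


def save_projections_tiff(stack: ProjectionStack, path: str | Path) -> None:
    tifffile.imwrite(path, stack.values.astype(np.float32), photometric="minisblack")
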