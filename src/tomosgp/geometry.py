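"""Acquisition geometry for digital breast tomosynthesis (DBT).

A DBT scanner holds the compressed breast on a stationary flat-panel
detector while the X-ray source sweeps a short C-shaped arc above it,
firing a cone beam from each of a handful of angular positions.

Coordinate conventions used throughout the package
--------------------------------------------------
* Right-handed frame; the detector occupies the plane ``Z = 0``.
* ``X`` runs along detector columns, ``Y`` along detector rows, which is
  also the source-motion direction; ``Z`` points up toward the source.
* The source arc lies in the ``YZ`` plane and rotates about
  ``arc_center`` (by default a point on the detector plane directly
  below the central source position).
* All lengths are millimetres; angles are degrees in configuration
  files and converted to radians internally.
* Indexing is 0-based; pixel/voxel positions refer to cell corners and
  cells are half-open boxes ``[corner, corner + pitch)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ScanGeometry",
    "VolumeGrid",
    "GeometryError",
    "source_position",
    "source_positions",
    "giotto_default_geometry",
    "validate",
    "load_geometry",
    "save_geometry",
]


class GeometryError(ValueError):
    """Raised when a geometry or grid violates an invariant."""


@dataclass(frozen=True)
class ScanGeometry:
    """C-arc acquisition geometry over a stationary flat detector.

    Parameters
    ----------
    source_detector_distance
        Height (mm) of the source above the detector plane at the
        central (0 deg) position.
    angles_deg
        Ordered, strictly increasing angular positions (degrees) of the
        source on the arc in the YZ plane; 0 deg is straight up.
    detector_rows, detector_cols
        Detector size ``n_y`` x ``n_x`` in pixels.
    detector_pitch_x, detector_pitch_y
        Pixel pitch (mm) along X (columns) and Y (rows).
    detector_origin
        XY offset (mm) of the corner of pixel (0, 0).
    arc_center
        3D point (mm) about which the source rotates; defaults to the
        detector-plane point below the central source position.
    """

    source_detector_distance: float
    angles_deg: tuple[float, ...]
    detector_rows: int
    detector_cols: int
    detector_pitch_x: float
    detector_pitch_y: float
    detector_origin: tuple[float, float] = (0.0, 0.0)
    arc_center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles_deg", tuple(float(a) for a in self.angles_deg))
        object.__setattr__(self, "detector_origin", tuple(float(v) for v in self.detector_origin))
        object.__setattr__(self, "arc_center", tuple(float(v) for v in self.arc_center))
        if self.n_angles < 1:
            raise GeometryError("angles_deg: need at least one angle")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise GeometryError("angles_deg: angles must be strictly increasing")
        if self.source_detector_distance <= 0:
            raise GeometryError("source_detector_distance: must be > 0")
        if self.detector_pitch_x <= 0 or self.detector_pitch_y <= 0:
            raise GeometryError("detector_pitch_x/detector_pitch_y: must be > 0")
        if self.detector_rows < 1 or self.detector_cols < 1:
            raise GeometryError("detector_rows/detector_cols: must be >= 1")
        if len(self.detector_origin) != 2:
            raise GeometryError("detector_origin: must be a 2-vector")
        if len(self.arc_center) != 3:
            raise GeometryError("arc_center: must be a 3-vector")

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @property
    def n_x(self) -> int:
        """Detector columns (along X)."""
        return self.detector_cols

    @property
    def n_y(self) -> int:
        """Detector rows (along Y, the source-motion direction)."""
        return self.detector_rows

    @property
    def arc_radius(self) -> float:
        """Distance (mm) from arc_center to the source."""
        return self.source_detector_distance - self.arc_center[2]

    def pixel_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel boundary coordinates along X (n_x+1) and Y (n_y+1), in mm."""
        x0, y0 = self.detector_origin
        xe = x0 + self.detector_pitch_x * np.arange(self.n_x + 1)
        ye = y0 + self.detector_pitch_y * np.arange(self.n_y + 1)
        return xe, ye


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel lattice for the reconstructed volume.

    ``origin`` is the corner of voxel (0, 0, 0) in the detector frame;
    ``dz`` is the slice thickness, typically much larger than the
    in-plane pitch in DBT (coarse depth resolution is intrinsic to the
    limited-angle geometry).
    """

    shape: tuple[int, int, int]  # (N_x, N_y, N_z)
    voxel_size: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))  # (dx, dy, dz) mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise GeometryError("shape: all voxel counts must be >= 1")
        if any(p <= 0 for p in self.voxel_size):
            raise GeometryError("voxel_size: all pitches must be > 0")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def z_top(self) -> float:
        return self.origin[2] + self.shape[2] * self.voxel_size[2]

    def x_edges(self) -> np.ndarray:
        return self.origin[0] + self.voxel_size[0] * np.arange(self.shape[0] + 1)

    def y_edges(self) -> np.ndarray:
        return self.origin[1] + self.voxel_size[1] * np.arange(self.shape[1] + 1)

    def slice_midplanes(self) -> np.ndarray:
        """Z of the mid-plane of each slice (length N_z)."""
        return self.origin[2] + self.voxel_size[2] * (np.arange(self.shape[2]) + 0.5)


def source_position(geometry: ScanGeometry, angle_index: int) -> np.ndarray:
    """Source position (mm) for one angular index.

    The central source sits ``source_detector_distance`` above the
    detector; position ``i`` is that point rotated by
    ``angles_deg[i]`` about ``arc_center`` within the YZ plane, so the
    X coordinate always equals ``arc_center[0]``.
    """
    if not 0 <= angle_index < geometry.n_angles:
        raise IndexError(
            f"angle_index {angle_index} out of range [0, {geometry.n_angles})"
        )
    theta = np.deg2rad(geometry.angles_deg[angle_index])
    cx, cy, cz = geometry.arc_center
    r = geometry.arc_radius
    return np.array([cx, cy + r * np.sin(theta), cz + r * np.cos(theta)])


def source_positions(geometry: ScanGeometry) -> np.ndarray:
    """All source positions as an (N_theta, 3) array."""
    return np.array([source_position(geometry, i) for i in range(geometry.n_angles)])


def giotto_default_geometry(**overrides) -> ScanGeometry:
    """Packaged preset mimicking a Giotto Class DBT unit.

    11 equispaced views on [-15, +15] degrees, source 690 mm above the
    detector, 3580 x 2812 detector with 0.085 mm pitch. Any field can
    be overridden by keyword.
    """
    params = dict(
        source_detector_distance=690.0,
        angles_deg=tuple(np.linspace(-15.0, 15.0, 11)),
        detector_rows=2812,
        detector_cols=3580,
        detector_pitch_x=0.085,
        detector_pitch_y=0.085,
    )
    params.update(overrides)
    return ScanGeometry(**params)


def validate(geometry: ScanGeometry, grid: VolumeGrid) -> tuple[ScanGeometry, VolumeGrid]:
    """Check the joint invariants of a geometry/grid pair.

    Returns the pair unchanged if every source position lies strictly
    above the top of the volume and the volume sits on or above the
    detector plane; raises :class:`GeometryError` naming the offending
    field otherwise. (Per-object invariants are enforced at
    construction.)
    """
    if grid.origin[2] < 0:
        raise GeometryError("origin: volume must not extend below the detector plane")
    for i in range(geometry.n_angles):
        sz = source_position(geometry, i)[2]
        if sz <= grid.z_top:
            raise GeometryError(
                f"source_detector_distance/shape: source at angle index {i} "
                f"(z={sz:.3f} mm) is not above the volume top (z={grid.z_top:.3f} mm)"
            )
    return geometry, grid


# ---------------------------------------------------------------------------
# config I/O

def _geometry_to_dict(geometry: ScanGeometry) -> dict:
    d = asdict(geometry)
    d["angles_deg"] = list(d["angles_deg"])
    d["detector_origin"] = list(d["detector_origin"])
    d["arc_center"] = list(d["arc_center"])
    return d


def save_geometry(geometry: ScanGeometry, path: str | Path) -> None:
    """Write a geometry to a YAML (or JSON, by extension) config file."""
    path = Path(path)
    d = _geometry_to_dict(geometry)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_geometry(path: str | Path) -> ScanGeometry:
    """Read a geometry config (YAML or JSON; lengths mm, angles degrees).

    The single string ``"giotto"`` in place of a mapping selects the
    packaged preset.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data == "giotto":
        return giotto_default_geometry()
    if isinstance(data, dict) and data.get("preset") == "giotto":
        overrides = {k: v for k, v in data.items() if k != "preset"}
        return giotto_default_geometry(**_coerce_geometry_fields(overrides))
    return ScanGeometry(**_coerce_geometry_fields(data))


def _coerce_geometry_fields(d: dict) -> dict:
    out = dict(d)
    for key in ("angles_deg", "detector_origin", "arc_center"):
        if key in out:
            out[key] = tuple(out[key])
    return out
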