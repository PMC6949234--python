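import numpy as np
import pytest

from tomosgp import ScanGeometry, VolumeGrid


def aligned_identity_system(n_x: int = 6, n_y: int = 5) -> tuple[ScanGeometry, VolumeGrid]:
    """Geometry/grid pair whose system matrix is the identity.

    One view straight down from an extremely distant source (effectively
    a parallel beam), detector pixels aligned 1:1 with the voxels of a
    single slice of unit thickness: each pixel footprint covers exactly
    its own voxel with weight dz = 1, and the obliquity factor rounds to
    1 in double precision.
    """
    geometry = ScanGeometry(
        source_detector_distance=1e12,
        angles_deg=(0.0,),
        detector_rows=n_y,
        detector_cols=n_x,
        detector_pitch_x=1.0,
        detector_pitch_y=1.0,
        detector_origin=(-0.5 * n_x, -0.5 * n_y),
    )
    grid = VolumeGrid(
        shape=(n_x, n_y, 1),
        voxel_size=(1.0, 1.0, 1.0),
        origin=(-0.5 * n_x, -0.5 * n_y, 0.0),
    )
    return geometry, grid


def small_cone_system(
    nx: int = 8, ny: int = 8, nz: int = 4, angles=(-10.0, 0.0, 10.0),
    det: tuple[int, int] | None = None, pitch: float = 1.0, height: float = 80.0,
) -> tuple[ScanGeometry, VolumeGrid]:
    """A desk-sized cone-beam system with the volume centered on the detector."""
    if det is None:
        det = (nx + 4, ny + 4)
    geometry = ScanGeometry(
        source_detector_distance=height,
        angles_deg=tuple(angles),
        detector_rows=det[1],
        detector_cols=det[0],
        detector_pitch_x=pitch,
        detector_pitch_y=pitch,
        detector_origin=(-0.5 * det[0] * pitch, -0.5 * det[1] * pitch),
    )
    grid = VolumeGrid(
        shape=(nx, ny, nz),
        voxel_size=(1.0, 1.0, 2.0),
        origin=(-0.5 * nx, -0.5 * ny, 3.0),
    )
    return geometry, grid


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


@pytest.fixture
def cone_system():
    return small_cone_system()
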