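"""Matrix-free distance-driven cone-beam projectors.

The tomographic model is a linear system ``A x = b`` where ``x`` is the
voxelized attenuation volume and ``b`` the stack of projection images.
``A`` is far too large (and too sparse) to store even for modest
volumes, so both the forward projection ``A x`` (volume -> detector)
and the backward projection ``A^T r`` (detector -> volume) recompute
the nonzero entries of ``A`` on the fly.

Weights follow the distance-driven (DD) model: for each volume slice
the detector-pixel boundaries are projected from the source onto the
slice mid-plane; a voxel's weight is the fractional overlap of its
footprint with the pixel footprint, times the effective path length
``dz / cos(phi)`` through the slab (``phi`` = angle between the pixel's
central ray and the Z axis). Because the detector and slice planes are
parallel, the footprint is an axis-aligned rectangle and the overlap
factorizes into independent X and Y interval overlaps; the projectors
exploit this by building one sparse 1D overlap matrix per axis, per
slice, per angle. Weights are effective intersection path lengths in
mm, so ``A x`` approximates the Beer-Lambert line integral.

The backward projector uses the transposes of the same sparse factors,
making it the exact adjoint of the forward projector up to rounding.
All arithmetic is double precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import ScanGeometry, VolumeGrid, source_position, validate

__all__ = [
    "Volume",
    "ProjectionStack",
    "SparseRow",
    "dd_row",
    "oracle_row",
    "forward_project",
    "back_project",
    "chunked_apply",
    "matrix_density",
]


@dataclass
class Volume:
    """Voxelized attenuation map (mm^-1), shape ``(N_x, N_y, N_z)``."""

    values: np.ndarray
    grid: VolumeGrid

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"volume shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")


@dataclass
class ProjectionStack:
    """Stack of line-integral images, shape ``(N_theta, n_y, n_x)``."""

    values: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        expected = (self.geometry.n_angles, self.geometry.n_y, self.geometry.n_x)
        if self.values.shape != expected:
            raise ValueError(
                f"projection shape {self.values.shape} does not match geometry {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("projections contain non-finite values")


@dataclass
class SparseRow:
    """Nonzeros of one row of the system matrix ``A``.

    One row corresponds to one (angle, detector pixel) pair; weights
    are effective intersection path lengths (mm) per voxel, indexed by
    flat C-order voxel index over ``(N_x, N_y, N_z)``.
    """

    voxel_indices: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.voxel_indices.shape != self.weights.shape:
            raise ValueError("voxel_indices and weights must have the same length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if len(np.unique(self.voxel_indices)) != len(self.voxel_indices):
            raise ValueError("voxel indices must be unique")


# ---------------------------------------------------------------------------
# geometric building blocks

def _interval_overlaps(src_edges: np.ndarray, dst_edges: np.ndarray) -> sp.csr_matrix:
    """Sparse (n_src x n_dst) matrix of 1D interval overlap lengths.

    Both edge arrays are strictly increasing; intervals are half-open,
    so zero-length overlaps (shared boundaries) contribute nothing.
    """
    n_src = len(src_edges) - 1
    n_dst = len(dst_edges) - 1
    lo = np.searchsorted(dst_edges, src_edges[:-1], side="right") - 1
    hi = np.searchsorted(dst_edges, src_edges[1:], side="left") - 1
    rows, cols, vals = [], [], []
    max_span = int(np.max(hi - lo, initial=0))
    for off in range(max_span + 1):
        j = lo + off
        valid = (j >= 0) & (j <= hi) & (j < n_dst)
        i = np.nonzero(valid)[0]
        if i.size == 0:
            continue
        jj = j[i]
        ov = np.minimum(src_edges[i + 1], dst_edges[jj + 1]) - np.maximum(
            src_edges[i], dst_edges[jj]
        )
        keep = ov > 0
        rows.append(i[keep])
        cols.append(jj[keep])
        vals.append(ov[keep])
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
    else:
        rows = cols = np.empty(0, dtype=np.int64)
        vals = np.empty(0)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n_src, n_dst))


def _path_factors(geometry: ScanGeometry, grid: VolumeGrid, source: np.ndarray) -> np.ndarray:
    """Per-pixel effective slab thickness ``dz / cos(phi)``, shape (n_y, n_x).

    ``phi`` is the obliquity of the pixel's central ray; the factor
    converts the slab thickness into the ray's path length through it.
    """
    xe, ye = geometry.pixel_edges()
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    sx, sy, sz = source
    dist = np.sqrt((xc[None, :] - sx) ** 2 + (yc[:, None] - sy) ** 2 + sz**2)
    return grid.voxel_size[2] * dist / sz


def _slice_factors(
    geometry: ScanGeometry, grid: VolumeGrid, source: np.ndarray, k: int
) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Normalized DD overlap factors (Wx, Wy) for slice ``k``.

    ``Wx[i, m]`` is the fraction of pixel column ``i``'s footprint on
    the slice mid-plane covered by voxel column ``m`` (likewise Wy for
    rows), so the DD weight of voxel (m, n, k) for pixel (j, i) is
    ``Wx[i, m] * Wy[j, n] * path_factor[j, i]``.
    """
    sx, sy, sz = source
    z_mid = grid.slice_midplanes()[k]
    if sz <= z_mid:
        raise ValueError("degenerate geometry: slice mid-plane not below the source")
    lam = (sz - z_mid) / sz  # magnification of the detector onto the slice plane
    xe, ye = geometry.pixel_edges()
    mx = sx + lam * (xe - sx)
    my = sy + lam * (ye - sy)
    fx = lam * geometry.detector_pitch_x
    fy = lam * geometry.detector_pitch_y
    Wx = _interval_overlaps(mx, grid.x_edges()) / fx
    Wy = _interval_overlaps(my, grid.y_edges()) / fy
    return Wx.tocsr(), Wy.tocsr()


# ---------------------------------------------------------------------------
# system-matrix rows

def dd_row(
    geometry: ScanGeometry,
    grid: VolumeGrid,
    angle_index: int,
    pixel_row: int,
    pixel_col: int,
) -> SparseRow:
    """Distance-driven weights of one system-matrix row.

    The row collects, over all slices, the contribution of every voxel
    to the projection onto detector pixel ``(pixel_row, pixel_col)``
    from view ``angle_index``. Only nonzero entries are returned.
    """
    if not 0 <= pixel_row < geometry.n_y:
        raise IndexError(f"pixel_row {pixel_row} out of range [0, {geometry.n_y})")
    if not 0 <= pixel_col < geometry.n_x:
        raise IndexError(f"pixel_col {pixel_col} out of range [0, {geometry.n_x})")
    src = source_position(geometry, angle_index)
    L = _path_factors(geometry, grid, src)[pixel_row, pixel_col]
    nx, ny, nz = grid.shape
    idx_parts, w_parts = [], []
    for k in range(nz):
        Wx, Wy = _slice_factors(geometry, grid, src, k)
        wx = Wx.getrow(pixel_col)
        wy = Wy.getrow(pixel_row)
        if wx.nnz == 0 or wy.nnz == 0:
            continue
        # same factor order as the vectorized projectors: (wy * x * wx) * L
        w = (wy.data[:, None] * wx.data[None, :]) * L
        ii, jj = np.meshgrid(wx.indices, wy.indices, indexing="xy")
        flat = np.ravel_multi_index(
            (ii.ravel(), jj.ravel(), np.full(ii.size, k)), (nx, ny, nz)
        )
        idx_parts.append(flat)
        w_parts.append(w.ravel())
    if idx_parts:
        return SparseRow(np.concatenate(idx_parts), np.concatenate(w_parts))
    return SparseRow(np.empty(0, dtype=np.int64), np.empty(0))


def oracle_row(
    geometry: ScanGeometry,
    grid: VolumeGrid,
    angle_index: int,
    pixel_row: int,
    pixel_col: int,
    subsamples: int = 32,
) -> SparseRow:
    """Brute-force reference row by dense ray sampling.

    Casts ``subsamples**2`` rays from the source through a stratified
    grid of points on the pixel area, computes the exact ray-box
    intersection length with every voxel by slab clipping, and averages
    per voxel. Slow but assumption-free; used to validate
    :func:`dd_row`.
    """
    if subsamples < 1:
        raise ValueError("subsamples must be >= 1")
    src = source_position(geometry, angle_index)
    xe, ye = geometry.pixel_edges()
    u = (np.arange(subsamples) + 0.5) / subsamples
    px = xe[pixel_col] + u * geometry.detector_pitch_x
    py = ye[pixel_row] + u * geometry.detector_pitch_y
    PX, PY = np.meshgrid(px, py, indexing="xy")
    targets = np.stack([PX.ravel(), PY.ravel(), np.zeros(PX.size)], axis=1)
    dirs = targets - src  # ray(t) = src + t * dir, detector hit at t = 1
    ray_len = np.linalg.norm(dirs, axis=1)

    def slab_window(edges: np.ndarray, s: float, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # entry/exit parameter of each ray for each 1D slab [edges[m], edges[m+1])
        with np.errstate(divide="ignore", invalid="ignore"):
            t0 = (edges[:-1][None, :] - s) / d[:, None]
            t1 = (edges[1:][None, :] - s) / d[:, None]
        lo = np.minimum(t0, t1)
        hi = np.maximum(t0, t1)
        parallel = d == 0
        if np.any(parallel):
            inside = (edges[:-1][None, :] <= s) & (s < edges[1:][None, :])
            lo[parallel] = np.where(inside[parallel], -np.inf, np.inf)
            hi[parallel] = np.where(inside[parallel], np.inf, -np.inf)
        return lo, hi

    lox, hix = slab_window(grid.x_edges(), src[0], dirs[:, 0])
    loy, hiy = slab_window(grid.y_edges(), src[1], dirs[:, 1])
    ze = grid.origin[2] + grid.voxel_size[2] * np.arange(grid.shape[2] + 1)
    loz, hiz = slab_window(ze, src[2], dirs[:, 2])
    t_in = np.maximum.reduce(
        np.broadcast_arrays(
            lox[:, :, None, None], loy[:, None, :, None], loz[:, None, None, :]
        )
    )
    t_out = np.minimum.reduce(
        np.broadcast_arrays(
            hix[:, :, None, None], hiy[:, None, :, None], hiz[:, None, None, :]
        )
    )
    lengths = np.clip(t_out - t_in, 0.0, None) * ray_len[:, None, None, None]
    weights = lengths.mean(axis=0)
    nz = np.nonzero(weights.ravel())[0]
    return SparseRow(nz, weights.ravel()[nz])


# ---------------------------------------------------------------------------
# matrix-free operators

def forward_project(x: Volume, geometry: ScanGeometry) -> ProjectionStack:
    """Apply ``A``: project a volume onto the detector for every view."""
    grid = x.grid
    validate(geometry, grid)
    vol = x.values
    nz = grid.shape[2]
    proj = np.zeros((geometry.n_angles, geometry.n_y, geometry.n_x))
    for a in range(geometry.n_angles):
        src = source_position(geometry, a)
        acc = np.zeros((geometry.n_y, geometry.n_x))
        for k in range(nz):
            Wx, Wy = _slice_factors(geometry, grid, src, k)
            acc += Wy @ vol[:, :, k].T @ Wx.T
        proj[a] = acc * _path_factors(geometry, grid, src)
    return ProjectionStack(proj, geometry)


def back_project(r: ProjectionStack, geometry: ScanGeometry, grid: VolumeGrid) -> Volume:
    """Apply ``A^T``: accumulate projections back into the volume.

    Uses the transposes of the same DD factors as
    :func:`forward_project`, so the pair satisfies the adjoint identity
    ``<A x, y> = <x, A^T y>`` to rounding accuracy.
    """
    validate(geometry, grid)
    if r.geometry is not geometry and r.values.shape != (
        geometry.n_angles,
        geometry.n_y,
        geometry.n_x,
    ):
        raise ValueError("projection stack shape does not match geometry")
    vol = np.zeros(grid.shape)
    for a in range(geometry.n_angles):
        src = source_position(geometry, a)
        g = r.values[a] * _path_factors(geometry, grid, src)
        for k in range(grid.shape[2]):
            Wx, Wy = _slice_factors(geometry, grid, src, k)
            vol[:, :, k] += (Wy.T @ g @ Wx).T
    return Volume(vol, grid)


def chunked_apply(
    operator: str,
    input_: Volume | ProjectionStack,
    geometry: ScanGeometry,
    grid: VolumeGrid,
    chunk_slices: int,
) -> ProjectionStack | Volume:
    """Apply FwP or BwP processing the volume in Z-chunks.

    ``operator`` is ``"fwp"`` (input is a :class:`Volume`) or ``"bwp"``
    (input is a :class:`ProjectionStack`). Chunks are contiguous blocks
    of at most ``chunk_slices`` slices processed independently — the
    memory-bounded evaluation scheme for volumes that do not fit on an
    accelerator — and the result agrees with the unchunked operator to
    rounding for every chunk size.
    """
    nz = grid.shape[2]
    if not 1 <= chunk_slices <= nz:
        raise ValueError(f"chunk_slices must be in [1, {nz}]")
    bounds = list(range(0, nz, chunk_slices)) + [nz]
    if operator == "fwp":
        if not isinstance(input_, Volume):
            raise TypeError("fwp expects a Volume")
        out = np.zeros((geometry.n_angles, geometry.n_y, geometry.n_x))
        for k0, k1 in zip(bounds[:-1], bounds[1:]):
            sub = _subgrid(grid, k0, k1)
            out += forward_project(Volume(input_.values[:, :, k0:k1], sub), geometry).values
        return ProjectionStack(out, geometry)
    if operator == "bwp":
        if not isinstance(input_, ProjectionStack):
            raise TypeError("bwp expects a ProjectionStack")
        out = np.zeros(grid.shape)
        for k0, k1 in zip(bounds[:-1], bounds[1:]):
            sub = _subgrid(grid, k0, k1)
            out[:, :, k0:k1] = back_project(input_, geometry, sub).values
        return Volume(out, grid)
    raise ValueError(f"unknown operator {operator!r}; expected 'fwp' or 'bwp'")


def _subgrid(grid: VolumeGrid, k0: int, k1: int) -> VolumeGrid:
    ox, oy, oz = grid.origin
    return VolumeGrid(
        shape=(grid.shape[0], grid.shape[1], k1 - k0),
        voxel_size=grid.voxel_size,
        origin=(ox, oy, oz + k0 * grid.voxel_size[2]),
    )


def matrix_density(geometry: ScanGeometry, grid: VolumeGrid) -> float:
    """Fraction of nonzero entries of ``A``.

    Counts the DD nonzeros of every row (every angle/pixel pair)
    exactly, using the separability of the footprint overlaps, and
    divides by ``N_d * N_v``. Intended for small-to-moderate
    geometries; full clinical-scale matrices have densities around
    1e-7.
    """
    validate(geometry, grid)
    nnz = 0
    for a in range(geometry.n_angles):
        src = source_position(geometry, a)
        for k in range(grid.shape[2]):
            Wx, Wy = _slice_factors(geometry, grid, src, k)
            # row (j, i) has cx[i] * cy[j] nonzeros in this slice, and
            # sum_{i,j} cx[i]*cy[j] factorizes
            cx = int(Wx.getnnz(axis=1).sum(dtype=np.int64))
            cy = int(Wy.getnnz(axis=1).sum(dtype=np.int64))
            nnz += cx * cy
    n_d = geometry.n_angles * geometry.n_x * geometry.n_y
    return nnz / (n_d * grid.n_voxels)
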