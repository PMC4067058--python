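"""Oriented Gaussian point-spread-function kernels and the sparse system matrix.

The forward model links the isotropic reconstruction target ``X`` to every
acquired slice voxel through one sparse row of PSF weights.  Rows are
normalized to sum to one so that a constant volume simulates to exactly that
constant and slice scales stay identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse

from .core import ImageGrid, SliceStack, Volume

__all__ = ["PSFSpec", "SystemMatrix", "default_psf", "build_system_matrix",
           "simulate_slices", "reconstruction_grid"]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
#: in-plane FWHM as a multiple of the in-plane voxel size (sinc main lobe fit)
INPLANE_FWHM_FACTOR = 1.2


@dataclass(frozen=True)
class PSFSpec:
    """3D Gaussian PSF given by per-axis FWHM in the slice frame (mm)."""

    fwhm_inplane_x: float
    fwhm_inplane_y: float
    fwhm_throughplane: float
    truncation_radius: float = 3.0  # in sigma units

    def __post_init__(self):
        for v in (self.fwhm_inplane_x, self.fwhm_inplane_y, self.fwhm_throughplane):
            if v <= 0:
                raise ValueError("PSF FWHM must be positive")
        if self.truncation_radius <= 0:
            raise ValueError("truncation radius must be positive")

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([self.fwhm_inplane_x, self.fwhm_inplane_y,
                         self.fwhm_throughplane]) * FWHM_TO_SIGMA


def default_psf(slice_thickness: float, inplane_spacing: float,
                truncation_radius: float = 3.0) -> PSFSpec:
    """PSF with through-plane FWHM = slice thickness and in-plane FWHM =
    1.2 x the in-plane voxel size."""
    if slice_thickness <= 0 or inplane_spacing <= 0:
        raise ValueError("slice thickness and in-plane spacing must be positive")
    fw = INPLANE_FWHM_FACTOR * inplane_spacing
    return PSFSpec(fw, fw, float(slice_thickness), truncation_radius)


class SystemMatrix:
    """Sparse forward operator mapping volume voxels to slice voxels.

    Rows are ordered slice-major; within a slice, voxels follow C-order of
    the 2D array, so row ``row_start[k] + flat`` belongs to in-slice voxel
    ``flat`` of slice ``k``.  Rows with no in-grid support are empty and
    flagged in ``empty_rows``.
    """

    def __init__(self, matrix: sparse.csr_matrix, row_start: np.ndarray,
                 slice_shapes: list[tuple[int, int]], grid: ImageGrid):
        self.matrix = matrix
        self.row_start = np.asarray(row_start)
        self.slice_shapes = slice_shapes
        self.grid = grid
        row_mass = np.asarray(matrix.sum(axis=1)).ravel()
        self.empty_rows = row_mass <= 0

    @property
    def n_slices(self) -> int:
        return len(self.slice_shapes)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def rows_for_slice(self, k: int) -> slice:
        return slice(int(self.row_start[k]), int(self.row_start[k + 1]))

    def slice_matrix(self, k: int) -> sparse.csr_matrix:
        return self.matrix[self.rows_for_slice(k)]

    def forward(self, values: np.ndarray) -> np.ndarray:
        """``M @ x`` over the flattened volume; empty rows map to NaN."""
        y = self.matrix @ np.asarray(values, dtype=float).ravel()
        y[self.empty_rows] = np.nan
        return y

    def adjoint(self, row_values: np.ndarray) -> np.ndarray:
        """``M.T @ y`` back onto the volume grid (empty rows contribute 0)."""
        y = np.asarray(row_values, dtype=float).copy()
        y[~np.isfinite(y)] = 0.0
        return (self.matrix.T @ y).reshape(self.grid.shape)

    def split_rows(self, row_values: np.ndarray) -> list[np.ndarray]:
        """Reshape a per-row vector into per-slice 2D arrays."""
        out = []
        for k, shp in enumerate(self.slice_shapes):
            out.append(np.asarray(row_values[self.rows_for_slice(k)]).reshape(shp))
        return out

    def to_text(self, path) -> None:
        """Debug dump as 'row,col,value' triplets (documented text format)."""
        coo = self.matrix.tocoo()
        with open(path, "w") as fh:
            fh.write("# row,col,value\n")
            for r, c, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{r},{c},{v:.17g}\n")


def _slice_rows(slc, grid: ImageGrid, psf: PSFSpec):
    """COO triplets (local row, volume col, weight) for one slice."""
    sig = psf.sigmas
    # PSF axes in world space follow the slice frame (rotated by the motion)
    R_w = slc.transform.rotation @ slc.grid.direction
    cov_w = (R_w * sig**2) @ R_w.T
    prec_w = (R_w / sig**2) @ R_w.T

    D = grid.direction
    S = np.asarray(grid.spacing)
    # covariance seen in (fractional) index space of the volume grid
    cov_idx = (D.T @ cov_w @ D) / np.outer(S, S)
    half = psf.truncation_radius * np.sqrt(np.diag(cov_idx))

    centers = grid.world_to_voxel(slc.world_centers())      # (n, 3)
    base = np.round(centers).astype(int)
    ranges = [np.arange(-int(np.ceil(h)), int(np.ceil(h)) + 1) for h in half]
    offs = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)

    n = centers.shape[0]
    pos = base[:, None, :] + offs[None, :, :]               # (n, m, 3)
    d_idx = pos - centers[:, None, :]
    d_w = (d_idx * S) @ D.T                                  # world displacement
    maha2 = np.einsum("nmi,ij,nmj->nm", d_w, prec_w, d_w)
    w = np.exp(-0.5 * maha2)
    w[maha2 > psf.truncation_radius**2] = 0.0

    inside = np.all((pos >= 0) & (pos < np.asarray(grid.shape)), axis=-1)
    w = np.where(inside, w, 0.0)

    # sigma -> 0 limit: keep a delta at the nearest in-grid voxel so thin
    # PSFs never silently lose slice voxels that do sit on the grid
    row_mass = w.sum(axis=1)
    dead = row_mass <= 0
    if np.any(dead):
        near_ok = np.all((base >= 0) & (base < np.asarray(grid.shape)), axis=-1)
        fix = dead & near_ok
        if np.any(fix):
            zero_off = int(np.flatnonzero(np.all(offs == 0, axis=1))[0])
            w[fix, zero_off] = 1.0
            row_mass = w.sum(axis=1)

    keep = w > 0
    rows = np.repeat(np.arange(n), keep.sum(axis=1))
    cols = np.ravel_multi_index(tuple(pos[keep].T), grid.shape)
    data = w[keep] / row_mass[rows]
    return rows, cols, data, n


def build_system_matrix(stacks: SliceStack | Sequence[SliceStack],
                        grid: ImageGrid, psf: PSFSpec | Sequence[PSFSpec]) -> SystemMatrix:
    """Build the row-normalized sparse PSF matrix for one or more stacks.

    ``psf`` may be a single spec (shared) or one spec per stack.
    """
    if isinstance(stacks, SliceStack):
        stacks = [stacks]
    if isinstance(psf, PSFSpec):
        psfs = [psf] * len(stacks)
    else:
        psfs = list(psf)
        if len(psfs) != len(stacks):
            raise ValueError("need one PSFSpec per stack")

    all_rows, all_cols, all_data = [], [], []
    row_start = [0]
    shapes: list[tuple[int, int]] = []
    offset = 0
    for stack, spec in zip(stacks, psfs):
        stack_has_support = False
        for slc in stack:
            r, c, d, n = _slice_rows(slc, grid, spec)
            if r.size:
                stack_has_support = True
            all_rows.append(r + offset)
            all_cols.append(c)
            all_data.append(d)
            offset += n
            row_start.append(offset)
            shapes.append(slc.values.shape)
        if not stack_has_support:
            raise ValueError(f"stack {stack.label!r} has no overlap with the "
                             "reconstruction grid")
    M = sparse.csr_matrix(
        (np.concatenate(all_data), (np.concatenate(all_rows), np.concatenate(all_cols))),
        shape=(offset, grid.n_voxels))
    return SystemMatrix(M, np.asarray(row_start), shapes, grid)


def simulate_slices(volume: Volume, M: SystemMatrix) -> list[np.ndarray]:
    """Simulate slice intensities ``sum_i m_ijk x_i`` from a volume.

    Returns one 2D array per slice; rows with no grid support are NaN.
    """
    if volume.grid.shape != M.grid.shape:
        raise ValueError("volume grid does not match the system matrix grid")
    return M.split_rows(M.forward(volume.values))


def reconstruction_grid(stacks: Sequence[SliceStack], spacing: float | None = None,
                        pad_voxels: int = 5) -> ImageGrid:
    """Isotropic axis-aligned grid covering all in-mask slice voxels.

    Default voxel size is the smallest in-plane spacing over the stacks;
    the extent is the world bounding box of masked slice voxels padded by
    ``pad_voxels`` voxels per side.
    """
    if spacing is None:
        spacing = min(s.inplane_spacing for st in stacks for s in st)
    los, his = [], []
    for st in stacks:
        for slc in st:
            pts = slc.world_centers()[slc.mask.ravel()]
            if pts.size:
                los.append(pts.min(axis=0))
                his.append(pts.max(axis=0))
    if not los:
        raise ValueError("no masked slice voxels to cover")
    lo = np.min(los, axis=0) - pad_voxels * spacing
    hi = np.max(his, axis=0) + pad_voxels * spacing
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
    return ImageGrid(tuple(shape), (spacing,) * 3, tuple(lo))
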