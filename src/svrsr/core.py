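"""World-anchored image grids, rigid transforms and image containers.

All geometry lives in world millimetres.  Voxel indices are zero-based and
follow the voxel-*center* convention: continuous index ``i`` maps to the
center of voxel ``i``.  Rotations are parameterized by three Euler angles
(radians) applied in ``R = Rz @ Ry @ Rx`` order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "RigidTransform",
    "ImageGrid",
    "Volume",
    "Slice",
    "SliceStack",
]

_ORTHO_TOL = 1e-9


def _euler_to_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _matrix_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    # inverse of Rz @ Ry @ Rx; gimbal lock handled by convention rz = 0
    sy = -R[2, 0]
    sy = np.clip(sy, -1.0, 1.0)
    ry = float(np.arcsin(sy))
    if abs(sy) < 1.0 - 1e-12:
        rx = float(np.arctan2(R[2, 1], R[2, 2]))
        rz = float(np.arctan2(R[1, 0], R[0, 0]))
    else:
        rx = float(np.arctan2(-R[1, 2], R[1, 1]))
        rz = 0.0
    return rx, ry, rz


class RigidTransform:
    """6-DOF rigid world-space motion: ``p -> R @ p + t``."""

    __slots__ = ("rotation", "translation")

    def __init__(self, rotation: np.ndarray | None = None,
                 translation: Sequence[float] | None = None):
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        if t.shape != (3,):
            raise ValueError("translation must be length 3")
        self.rotation = R
        self.translation = t

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_params(cls, params: Sequence[float]) -> "RigidTransform":
        """Build from ``(rx, ry, rz, tx, ty, tz)``; angles in radians."""
        rx, ry, rz, tx, ty, tz = [float(v) for v in params]
        return cls(_euler_to_matrix(rx, ry, rz), (tx, ty, tz))

    @classmethod
    def from_matrix(cls, H: np.ndarray) -> "RigidTransform":
        H = np.asarray(H, dtype=float)
        if H.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return cls(H[:3, :3], H[:3, 3])

    @classmethod
    def about_center(cls, params: Sequence[float],
                     center: Sequence[float]) -> "RigidTransform":
        """Rigid motion whose rotation pivots about ``center`` (world mm)."""
        rx, ry, rz, tx, ty, tz = [float(v) for v in params]
        R = _euler_to_matrix(rx, ry, rz)
        c = np.asarray(center, dtype=float)
        t = c - R @ c + np.array([tx, ty, tz])
        return cls(R, t)

    # -- conversions --------------------------------------------------
    def to_params(self) -> np.ndarray:
        rx, ry, rz = _matrix_to_euler(self.rotation)
        return np.array([rx, ry, rz, *self.translation])

    def to_matrix(self) -> np.ndarray:
        H = np.eye(4)
        H[:3, :3] = self.rotation
        H[:3, 3] = self.translation
        return H

    # -- algebra ------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to points of shape ``(..., 3)``."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``(a.compose(b))(p) == a(b(p))``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def copy(self) -> "RigidTransform":
        return RigidTransform(self.rotation.copy(), self.translation.copy())

    def __repr__(self) -> str:  # pragma: no cover
        rx, ry, rz = np.degrees(_matrix_to_euler(self.rotation))
        t = self.translation
        return (f"RigidTransform(rot=({rx:.2f},{ry:.2f},{rz:.2f})deg, "
                f"t=({t[0]:.2f},{t[1]:.2f},{t[2]:.2f})mm)")


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Functional alias: ``compose(a, b)(p) == a(b(p))``."""
    return a.compose(b)


@dataclass(frozen=True)
class ImageGrid:
    """Regular 3D sampling grid anchored in world space.

    ``origin`` is the world position of the *center* of voxel (0, 0, 0);
    ``direction`` columns are the world-space axes of the grid.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        D = np.asarray(self.direction, dtype=float)
        object.__setattr__(self, "direction", D)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError("shape must be 3 positive ints")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if D.shape != (3, 3) or abs(abs(np.linalg.det(D)) - 1.0) > 1e-9 \
                or not np.allclose(D @ D.T, np.eye(3), atol=1e-9):
            raise ValueError("direction must be orthonormal with |det| = 1")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_world(self, index: np.ndarray) -> np.ndarray:
        """Affine map of (continuous) voxel indices, shape ``(..., 3)``."""
        idx = np.asarray(index, dtype=float)
        return (idx * np.asarray(self.spacing)) @ self.direction.T + np.asarray(self.origin)

    def world_to_voxel(self, point: np.ndarray) -> np.ndarray:
        p = np.asarray(point, dtype=float) - np.asarray(self.origin)
        return (p @ self.direction) / np.asarray(self.spacing)

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world affine (NIfTI style, center convention)."""
        A = np.eye(4)
        A[:3, :3] = self.direction * np.asarray(self.spacing)
        A[:3, 3] = self.origin
        return A

    def voxel_centers(self) -> np.ndarray:
        """World positions of all voxel centers, shape ``(n_voxels, 3)``."""
        idx = np.stack(np.meshgrid(*[np.arange(s) for s in self.shape],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        return self.voxel_to_world(idx)

    def transformed(self, t: RigidTransform) -> "ImageGrid":
        """The grid rigidly moved by ``t`` (same shape/spacing)."""
        return ImageGrid(self.shape, self.spacing,
                         tuple(t.apply(np.asarray(self.origin))),
                         t.rotation @ self.direction)


@dataclass
class Volume:
    """Scalar 3D image on a world-anchored grid."""

    grid: ImageGrid
    values: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape does not match grid")

    def copy(self) -> "Volume":
        return Volume(self.grid, self.values.copy(),
                      None if self.mask is None else self.mask.copy())


class Slice:
    """One acquired 2D slice embedded in 3D world space.

    ``grid`` describes the slice's nominal (motion-free) plane: shape
    ``(n0, n1, 1)``, in-plane axes in columns 0-1 of the direction matrix
    and the through-plane normal in column 2.  ``transform`` is the current
    rigid motion estimate applied on top: a slice voxel ``(a, b)`` sits at
    ``transform(grid.voxel_to_world((a, b, 0)))`` in the world.
    """

    def __init__(self, values: np.ndarray, grid: ImageGrid,
                 thickness: float, transform: RigidTransform | None = None,
                 mask: np.ndarray | None = None):
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("slice values must be 2D")
        if grid.shape != (*self.values.shape, 1):
            raise ValueError("slice grid must have shape (n0, n1, 1)")
        if thickness <= 0:
            raise ValueError("thickness must be positive")
        self.grid = grid
        self.thickness = float(thickness)
        self.transform = transform.copy() if transform is not None else RigidTransform.identity()
        self.mask = (np.ones(self.values.shape, dtype=bool) if mask is None
                     else np.asarray(mask, dtype=bool))
        if self.mask.shape != self.values.shape:
            raise ValueError("slice mask shape mismatch")
        self.scale: float = 1.0
        self.bias = np.zeros(self.values.shape)  # log-domain field b_jk
        self.posteriors = np.ones(self.values.shape)
        self.slice_posterior: float = 1.0
        self.excluded: bool = False
        self.meta: dict = {}

    @property
    def inplane_spacing(self) -> float:
        return self.grid.spacing[0]

    def corrected(self) -> np.ndarray:
        """Scaled and bias-corrected intensities ``s * exp(-b) * y``."""
        return self.scale * np.exp(-self.bias) * self.values

    def world_centers(self) -> np.ndarray:
        """World positions of all slice voxel centers (C-order, (n, 3))."""
        n0, n1 = self.values.shape
        a, b = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
        idx = np.stack([a.ravel(), b.ravel(), np.zeros(a.size)], axis=-1)
        return self.transform.apply(self.grid.voxel_to_world(idx))

    def copy(self) -> "Slice":
        s = Slice(self.values.copy(), self.grid, self.thickness,
                  self.transform, self.mask.copy())
        s.scale = self.scale
        s.bias = self.bias.copy()
        s.posteriors = self.posteriors.copy()
        s.slice_posterior = self.slice_posterior
        s.excluded = self.excluded
        s.meta = dict(self.meta)
        return s


class SliceStack:
    """Ordered collection of slices sharing acquisition geometry."""

    def __init__(self, slices: Sequence[Slice], label: str = "",
                 transform: RigidTransform | None = None):
        slices = list(slices)
        if not slices:
            raise ValueError("a stack needs at least one slice")
        sp = slices[0].inplane_spacing
        th = slices[0].thickness
        for s in slices:
            if abs(s.inplane_spacing - sp) > 1e-9 or abs(s.thickness - th) > 1e-9:
                raise ValueError("all slices in a stack must share spacing and thickness")
        self.slices = slices
        self.label = label
        self.transform = transform.copy() if transform is not None else RigidTransform.identity()

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self):
        return iter(self.slices)

    def __getitem__(self, i: int) -> Slice:
        return self.slices[i]

    def copy(self) -> "SliceStack":
        return SliceStack([s.copy() for s in self.slices], self.label, self.transform)
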