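"""NIfTI and plain-text readers/writers plus stack preprocessing."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .core import ImageGrid, RigidTransform, Slice, SliceStack, Volume
from .register import RegistrationError, RegistrationSettings, register_stack_to_template

__all__ = ["read_volume", "write_volume", "read_stack", "write_stack",
           "read_transforms", "write_transforms", "preprocess",
           "stack_to_volume"]

_AFFINE_ORTHO_TOL = 1e-3


def _grid_from_affine(affine: np.ndarray, shape) -> ImageGrid:
    A = np.asarray(affine, dtype=float)
    lin = A[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("degenerate affine: zero column norm")
    direction = lin / spacing
    if not np.allclose(direction.T @ direction, np.eye(3), atol=_AFFINE_ORTHO_TOL):
        raise ValueError("non-orthogonal affine beyond tolerance")
    # re-orthonormalize exactly so grid invariants hold at 1e-9
    u, _, vt = np.linalg.svd(direction)
    direction = u @ vt
    return ImageGrid(tuple(shape), tuple(spacing), tuple(A[:3, 3]), direction)


def read_volume(path) -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D: {path}")
    return Volume(_grid_from_affine(img.affine, data.shape), data)


def write_volume(volume: Volume, path) -> None:
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32),
                             volume.grid.affine()), str(path))


def read_mask(path) -> Volume:
    v = read_volume(path)
    v.mask = v.values > 0.5
    return v


def read_stack(path, thickness: float | None = None, label: str = "") -> SliceStack:
    """Load a 3D NIfTI as a stack of 2D slices along the third axis.

    Slice thickness defaults to the through-plane spacing from the header.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D stack, got {data.ndim}D: {path}")
    grid = _grid_from_affine(img.affine, data.shape)
    if thickness is None:
        thickness = grid.spacing[2]
    slices = []
    for j in range(data.shape[2]):
        sgrid = ImageGrid((data.shape[0], data.shape[1], 1), grid.spacing,
                          tuple(grid.voxel_to_world((0.0, 0.0, float(j)))),
                          grid.direction)
        slc = Slice(data[:, :, j], sgrid, thickness)
        slc.meta = {"stack": label or str(path), "index": j}
        slices.append(slc)
    return SliceStack(slices, label=label or Path(str(path)).stem)


def write_stack(stack: SliceStack, path) -> None:
    """Write the raw slice values back as one 3D NIfTI (nominal geometry)."""
    data = np.stack([s.values for s in stack], axis=2)
    first = stack.slices[0]
    grid = first.grid
    step = first.thickness  # contiguous by construction of read_stack
    if len(stack) > 1:
        d = stack.slices[1].grid.origin
        step = float(np.linalg.norm(np.asarray(d) - np.asarray(grid.origin)))
    g3 = ImageGrid(data.shape, (grid.spacing[0], grid.spacing[1], step or first.thickness),
                   grid.origin, grid.direction)
    nib.save(nib.Nifti1Image(data.astype(np.float32), g3.affine()), str(path))


def stack_to_volume(stack: SliceStack, mask: bool = True) -> Volume:
    """View a stack as a coarse 3D volume (for volumetric pre-registration)."""
    data = np.stack([s.values for s in stack], axis=2)
    first = stack.slices[0]
    step = first.thickness
    if len(stack) > 1:
        step = float(np.linalg.norm(np.asarray(stack.slices[1].grid.origin)
                                    - np.asarray(first.grid.origin)))
    grid = ImageGrid(data.shape, (first.grid.spacing[0], first.grid.spacing[1],
                                  step or first.thickness),
                     first.grid.origin, first.grid.direction)
    m = np.stack([s.mask for s in stack], axis=2) if mask else None
    return Volume(grid, data, m)


def write_transforms(transforms: Sequence[RigidTransform], path) -> None:
    """One 6-DOF row per slice: rx ry rz (rad) tx ty tz (mm)."""
    with open(path, "w") as fh:
        fh.write("# rx_rad ry_rad rz_rad tx_mm ty_mm tz_mm\n")
        for t in transforms:
            fh.write(" ".join(f"{v:.17g}" for v in t.to_params()) + "\n")


def read_transforms(path) -> list[RigidTransform]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(RigidTransform.from_params([float(v) for v in line.split()]))
    return out


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonify)


def write_slice_report_tsv(stacks, path) -> None:
    """Per-slice diagnostics: id, scale, potential, slice posterior, excluded."""
    with open(path, "w") as fh:
        fh.write("stack\tslice\tscale\tpotential\tslice_posterior\texcluded\n")
        for i, stack in enumerate(stacks):
            for j, s in enumerate(stack):
                pot = s.meta.get("potential")
                fh.write(f"{i}\t{j}\t{s.scale:.6g}\t"
                         f"{'' if pot is None else format(pot, '.6g')}\t"
                         f"{s.slice_posterior:.6g}\t{int(s.excluded)}\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _transfer_mask(stack: SliceStack, template: Volume,
                   stack_to_template: RigidTransform, threshold: float = 0.5) -> None:
    tmask = (template.mask if template.mask is not None
             else template.values > 0).astype(float)
    for slc in stack:
        pts = slc.world_centers()
        idx = template.grid.world_to_voxel(stack_to_template.apply(pts))
        vals = map_coordinates(tmask, idx.T, order=1, mode="constant")
        slc.mask = vals.reshape(slc.values.shape) > threshold


def preprocess(stacks: list[SliceStack], template_mask: Volume,
               template_index: int = 0, target_mean: float = 100.0,
               mask_smooth_mm: float = 2.0,
               settings: RegistrationSettings | None = None,
               skip_registration: bool = False) -> list[SliceStack]:
    """Mask, co-register and intensity-normalize the input stacks.

    The template mask is Gaussian-smoothed and re-thresholded, every other
    stack is volumetrically registered to the template stack (failures drop
    the stack with a warning in its metadata), the mask is transferred to
    all slices, and each stack is globally rescaled so that its masked mean
    intensity equals ``target_mean``.
    """
    settings = settings or RegistrationSettings()
    if template_mask.mask is None or not template_mask.mask.any():
        raise ValueError("template mask is empty")
    sm = gaussian_filter(template_mask.mask.astype(float),
                         mask_smooth_mm / np.asarray(template_mask.grid.spacing))
    smooth_mask = Volume(template_mask.grid, sm, sm > 0.5)

    # registration target: the template *stack's* anatomy under the mask
    tvol = stack_to_volume(stacks[template_index], mask=False)
    idx = template_mask.grid.world_to_voxel(tvol.grid.voxel_centers())
    on_stack = map_coordinates(sm, idx.T, order=1, mode="constant")
    template = Volume(tvol.grid, tvol.values,
                      on_stack.reshape(tvol.grid.shape) > 0.5)
    if not template.mask.any():
        raise ValueError("mask does not overlap the template stack")

    out = []
    for i, stack in enumerate(stacks):
        stack = stack.copy()
        if i == template_index or skip_registration:
            t = RigidTransform.identity()
        else:
            moving = stack_to_volume(stack, mask=False)
            # provisional foreground mask: input stacks arrive unmasked
            moving.mask = moving.values > 0.1 * np.percentile(moving.values, 99)
            try:
                t = register_stack_to_template(moving, template, settings)
            except RegistrationError:
                continue  # stack dropped
        stack.transform = t
        for slc in stack:
            # fold the stack-level alignment into each slice's pose estimate
            slc.transform = t.compose(slc.transform)
        _transfer_mask(stack, smooth_mask, RigidTransform.identity())
        vals = np.concatenate([s.values[s.mask].ravel() for s in stack
                               if s.mask.any()] or [np.zeros(1)])
        mean = vals.mean()
        if mean > 0:
            factor = target_mean / mean
            for slc in stack:
                slc.values = slc.values * factor
        out.append(stack)
    if not out:
        raise ValueError("all stacks failed preprocessing")
    return out
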