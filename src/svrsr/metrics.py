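"""Quantitative evaluation: NRMSE, PSNR, target registration error, and the
leave-one-out protocol for data without a ground-truth volume."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import RigidTransform, Slice, SliceStack, Volume
from .psf import build_system_matrix, default_psf
from .intensity import BiasSettings, update_bias, update_scales
from .register import RegistrationSettings, register_slice_to_volume

__all__ = ["EvaluationResult", "nrmse", "psnr", "tre", "leave_one_out",
           "match_volume_to_reference", "tre_included_mask"]

MIN_ROI_VOXELS = 50  # inclusion criterion 3: enough in-mask voxels to register


@dataclass
class EvaluationResult:
    nrmse: float
    psnr: float
    tre_mm: float | None = None
    per_slice_tre: np.ndarray | None = None
    excluded: list = field(default_factory=list)


def _masked(x: Volume, mask: np.ndarray | None):
    if mask is None:
        mask = x.mask if x.mask is not None else np.ones(x.values.shape, bool)
    return mask


def nrmse(recon: Volume, reference: Volume, mask: np.ndarray | None = None) -> float:
    """RMS intensity error divided by the reference's mean intensity."""
    if recon.grid.shape != reference.grid.shape:
        raise ValueError("volumes must share a grid")
    m = _masked(reference, mask)
    diff = recon.values[m] - reference.values[m]
    mean_ref = reference.values[m].mean()
    if mean_ref == 0:
        raise ValueError("reference mean intensity is zero")
    return float(np.sqrt((diff**2).mean()) / mean_ref)


def psnr(recon: Volume, reference: Volume, mask: np.ndarray | None = None) -> float:
    """``20 log10(MAX / RMSE)`` with MAX the reference maximum."""
    m = _masked(reference, mask)
    diff = recon.values[m] - reference.values[m]
    rmse = float(np.sqrt((diff**2).mean()))
    if rmse == 0:
        return float("inf")
    return float(20.0 * np.log10(reference.values.max() / rmse))


def tre_included_mask(labels: Sequence[str] | None,
                      slices: Sequence[Slice]) -> np.ndarray:
    """Apply the three exclusion criteria: corrupted, displaced, tiny ROI."""
    inc = np.ones(len(slices), dtype=bool)
    if labels is not None:
        lab = np.asarray(labels)
        inc &= (lab != "corrupted") & (lab != "displaced")
    inc &= np.array([int(s.mask.sum()) >= MIN_ROI_VOXELS for s in slices])
    return inc


def tre(true_transforms: Sequence[RigidTransform],
        est_transforms: Sequence[RigidTransform],
        slices: Sequence[Slice],
        labels: Sequence[str] | None = None,
        included: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Mean Euclidean displacement between true and estimated slice poses.

    The mean is taken over all in-ROI voxels of the included slices
    (voxel-count weighted); per-slice means are returned alongside.
    Excluded slices get NaN per-slice TRE.
    """
    if included is None:
        included = tre_included_mask(labels, slices)
    per_slice = np.full(len(slices), np.nan)
    total, count = 0.0, 0
    for k, (tt, te, slc) in enumerate(zip(true_transforms, est_transforms, slices)):
        msk = slc.mask.ravel()
        if not msk.any():
            continue
        n0, n1 = slc.values.shape
        a, b = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
        idx = np.stack([a.ravel(), b.ravel(), np.zeros(a.size)], axis=-1)[msk]
        pts = slc.grid.voxel_to_world(idx)
        d = np.linalg.norm(tt.apply(pts) - te.apply(pts), axis=1)
        per_slice[k] = float(d.mean())
        if included[k]:
            total += float(d.sum())
            count += d.size
    if count == 0:
        raise ValueError("no included slices for TRE")
    return total / count, per_slice


def match_volume_to_reference(recon: Volume, reference: Volume,
                              mask: np.ndarray | None = None,
                              bias_sigma_mm: float = 12.0) -> Volume:
    """Scale and differential-bias match a reconstruction to a reference.

    The same smoothed weighted log-residual machinery used for slices,
    applied once in 3D: global gain first, then a Gaussian-smooth
    multiplicative field estimated from ``log(ref / recon)``.
    """
    m = _masked(reference, mask)
    x = recon.values.copy()
    pos = m & (x > 0) & (reference.values > 0)
    if not pos.any():
        return Volume(recon.grid, x, recon.mask)
    gain = float((reference.values[pos] * x[pos]).sum() / (x[pos] ** 2).sum())
    x = gain * x
    r = np.zeros_like(x)
    r[pos] = np.log(reference.values[pos] / x[pos])
    w = np.where(pos, x, 0.0)
    sig = bias_sigma_mm / np.asarray(recon.grid.spacing)
    num = gaussian_filter(w * r, sig, mode="constant")
    den = gaussian_filter(w, sig, mode="constant")
    good = den > 1e-12 * w.max()
    b = np.zeros_like(x)
    b[good] = num[good] / den[good]
    b[pos] -= b[pos].mean()
    return Volume(recon.grid, x * np.exp(np.where(pos, b, 0.0)), recon.mask)


def leave_one_out(volume: Volume, held_out: SliceStack,
                  reg_settings: RegistrationSettings | None = None,
                  bias: BiasSettings | None = None,
                  max_alternations: int = 10, rel_tol: float = 1e-4,
                  register: bool = True) -> tuple[float, dict]:
    """Score a reconstruction against a held-out stack.

    Alternates slice-to-volume registration of the held-out slices with
    intensity matching until the sum of squared differences between
    held-out and simulated slices stops improving, then returns the NRMSE
    over held-out slice voxels normalized by the volume's mean intensity.
    """
    reg_settings = reg_settings or RegistrationSettings()
    bias = bias or BiasSettings()
    stack = held_out.copy()
    slices = list(stack)
    psf = default_psf(stack.slices[0].thickness, stack.slices[0].inplane_spacing)
    history = []
    prev = np.inf
    for _ in range(max_alternations):
        if register:
            for slc in slices:
                register_slice_to_volume(slc, volume, reg_settings)
        M = build_system_matrix(stack, volume.grid, psf)
        sim_rows = M.forward(volume.values)
        sim2d = M.split_rows(sim_rows)
        update_scales(slices, sim2d)
        update_bias(slices, sim2d, bias)
        ssd, n = 0.0, 0
        for slc, sim in zip(slices, sim2d):
            valid = slc.mask & np.isfinite(sim)
            d = slc.corrected()[valid] - sim[valid]
            ssd += float((d**2).sum())
            n += d.size
        history.append(ssd)
        if prev - ssd < rel_tol * max(prev, 1e-30):
            break
        prev = ssd
    vm = volume.mask if volume.mask is not None else np.ones(volume.values.shape, bool)
    mean_int = float(volume.values[vm].mean())
    value = float(np.sqrt(ssd / n) / mean_int)
    return value, {"ssd_history": history, "n_voxels": n}


def leave_one_out_from_stacks(stacks: Sequence[SliceStack], held_out_index: int,
                              recon_settings=None,
                              reg_settings: RegistrationSettings | None = None,
                              **kwargs) -> tuple[float, dict]:
    """Reconstruct from all stacks but one and score against the held-out one."""
    from .psf import reconstruction_grid
    from .superres import ReconSettings, reconstruct

    if len(stacks) < 2:
        raise ValueError("leave-one-out needs at least 2 stacks")
    retained = [st for i, st in enumerate(stacks) if i != held_out_index]
    grid = reconstruction_grid(retained)
    volume, _ = reconstruct(retained, grid, recon_settings or ReconSettings())
    return leave_one_out(volume, stacks[held_out_index], reg_settings, **kwargs)
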