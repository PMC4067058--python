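"""Synthetic phantom generation and motion-corrupted acquisition simulation.

Emulates the evaluation protocol: thick slices sampled through a known
volume via the oriented PSF, per-slice rigid motion, additive Gaussian noise
with sigma proportional to the volume mean, smooth multiplicative bias
fields, per-slice scaling factors, plus deliberately displaced and corrupted
outlier slices with recorded ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import ImageGrid, RigidTransform, Slice, SliceStack, Volume
from .psf import build_system_matrix, default_psf, simulate_slices

__all__ = ["SimulationSpec", "GroundTruth", "make_phantom",
           "simulate_acquisition", "default_orientations"]

#: "beyond capture range" displacement applied to outlier slices
DISPLACEMENT_TRANSLATION_MM = 15.0
DISPLACEMENT_ROTATION_DEG = 30.0


def default_orientations(n: int = 3) -> list[RigidTransform]:
    """n stack orientations; the first three are axis-aligned orthogonal."""
    quarter = np.pi / 2
    base = [
        RigidTransform.identity(),                                  # axial
        RigidTransform.from_params((quarter, 0, 0, 0, 0, 0)),       # coronal
        RigidTransform.from_params((0, quarter, 0, 0, 0, 0)),       # sagittal
    ]
    eighth = np.pi / 4
    extra = [
        RigidTransform.from_params((eighth, 0, 0, 0, 0, 0)),
        RigidTransform.from_params((0, eighth, 0, 0, 0, 0)),
        RigidTransform.from_params((0, 0, eighth, 0, 0, 0)).compose(
            RigidTransform.from_params((eighth, 0, 0, 0, 0, 0))),
    ]
    return (base + extra)[:n]


@dataclass
class SimulationSpec:
    """Full description of one synthetic acquisition draw."""

    orientations: list[RigidTransform] = field(default_factory=default_orientations)
    slices_per_stack: int = 26
    slice_thickness: float = 3.0
    inplane_spacing: float = 1.0
    slice_gap: float = 0.0                 # negative = overlap
    noise_fraction: float = 0.025          # sigma = fraction * mean(volume)
    bias_sigma_mm: float = 12.0
    bias_amplitude: float = 0.05           # target RMS of the log bias field
    scale_range: tuple[float, float] = (0.8, 1.2)
    n_displaced: int = 6                   # grossly displaced outlier slices
    n_corrupted: int = 5                   # ghosting-corrupted slices
    max_rotation_deg: float = 4.0
    max_translation_mm: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.scale_range[0] > self.scale_range[1]:
            raise ValueError("scale range lo must be <= hi")
        if self.n_displaced < 0 or self.n_corrupted < 0:
            raise ValueError("outlier counts must be >= 0")
        if self.slice_thickness <= 0 or self.inplane_spacing <= 0:
            raise ValueError("slice geometry must be positive")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the reconstructor must recover."""

    volume: Volume
    transforms: list[list[RigidTransform]]   # true motion per stack, per slice
    scales: np.ndarray                       # multiplier applied per slice (flat)
    biases: list[np.ndarray]                 # log bias applied per slice (flat order)
    labels: np.ndarray                       # 'clean' | 'displaced' | 'corrupted'

    def flat_transforms(self) -> list[RigidTransform]:
        return [t for ts in self.transforms for t in ts]


def make_phantom(size_mm: float = 64.0, spacing_mm: float = 1.0,
                 seed: int = 0) -> Volume:
    """Nested-ellipsoid phantom with >= 3 tissue levels and a bright rim.

    Deterministic for a fixed seed; intensities lie in [0, ~120] with the
    background at zero.  The volume is centered on the world origin.
    """
    if size_mm <= 0 or spacing_mm <= 0:
        raise ValueError("size and spacing must be positive")
    n = int(round(size_mm / spacing_mm))
    shape = (n, n, n)
    half = (n - 1) / 2.0
    grid = ImageGrid(shape, (spacing_mm,) * 3,
                     (-half * spacing_mm,) * 3)
    ax = (np.arange(n) - half) * spacing_mm
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    semi = np.array([0.44, 0.40, 0.42]) * size_mm
    rho = np.sqrt((X / semi[0]) ** 2 + (Y / semi[1]) ** 2 + (Z / semi[2]) ** 2)

    vals = np.zeros(shape)
    vals[rho < 1.0] = 140.0                # bright rim (skull analog)
    vals[rho < 0.92] = 105.0               # cortex band
    vals[rho < 0.70] = 65.0                # deep tissue
    vals[rho < 0.30] = 20.0                # ventricle analog

    rng = np.random.default_rng(seed)
    # asymmetric internal blobs break the ellipsoids' near-rotational
    # symmetry, without which slice rotations would be unidentifiable
    n_blobs = 6
    blob_centers = rng.uniform(-0.55, 0.55, (n_blobs, 3)) * semi
    blob_radii = rng.uniform(0.08, 0.16, n_blobs) * size_mm
    blob_levels = rng.uniform(-15.0, 15.0, n_blobs)
    pos = np.stack([X, Y, Z], axis=-1)
    interior = rho < 0.88
    for c, r, lv in zip(blob_centers, blob_radii, blob_levels):
        d2 = ((pos - c) ** 2).sum(axis=-1)
        vals += np.where(interior & (d2 < r * r), lv, 0.0)
    texture = gaussian_filter(rng.standard_normal(shape), 1.5 / spacing_mm)
    sd = texture.std()
    if sd > 0:
        # texture comparable to tissue contrast (cortical-fold analog); a
        # texture-poor target leaves slice rotations nearly unconstrained
        vals += np.where(rho < 1.0, 15.0 * texture / sd, 0.0)
    # soften tissue interfaces: step edges sharper than anything a real
    # acquisition could produce would dominate the forward-model residuals
    vals = gaussian_filter(vals, 0.8 / spacing_mm)
    vals = np.clip(vals, 0.0, None)
    return Volume(grid, vals, rho < 1.0)


def _stack_geometry(volume: Volume, orientation: RigidTransform,
                    spec: SimulationSpec):
    """Nominal slice grids of one stack, centered on the volume's center."""
    g = volume.grid
    center = g.voxel_to_world((np.asarray(g.shape) - 1) / 2.0)
    extent = float(np.max(np.asarray(g.shape) * np.asarray(g.spacing)))
    n_ip = int(np.ceil(extent / spec.inplane_spacing)) + 4
    step = spec.slice_thickness + spec.slice_gap
    D = orientation.rotation
    grids = []
    for j in range(spec.slices_per_stack):
        z = (j - (spec.slices_per_stack - 1) / 2.0) * step
        origin = (center + D[:, 2] * z
                  - D[:, 0] * (n_ip - 1) / 2.0 * spec.inplane_spacing
                  - D[:, 1] * (n_ip - 1) / 2.0 * spec.inplane_spacing)
        grids.append(ImageGrid((n_ip, n_ip, 1),
                               (spec.inplane_spacing, spec.inplane_spacing,
                                spec.slice_thickness),
                               tuple(origin), D))
    return grids, center


def _draw_motion(rng: np.random.Generator, spec: SimulationSpec,
                 center: np.ndarray) -> RigidTransform:
    rot = np.radians(rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg, 3))
    tra = rng.uniform(-spec.max_translation_mm, spec.max_translation_mm, 3)
    return RigidTransform.about_center((*rot, *tra), center)


def _draw_displacement(rng: np.random.Generator, center: np.ndarray) -> RigidTransform:
    axis_rot = np.zeros(3)
    axis_rot[rng.integers(3)] = np.radians(DISPLACEMENT_ROTATION_DEG) * rng.choice([-1, 1])
    t = rng.standard_normal(3)
    t *= DISPLACEMENT_TRANSLATION_MM / np.linalg.norm(t)
    return RigidTransform.about_center((*axis_rot, *t), center)


def _smooth_bias(rng: np.random.Generator, shape, spacing: float,
                 sigma_mm: float, amplitude: float, mask: np.ndarray) -> np.ndarray:
    b = gaussian_filter(rng.standard_normal(shape), sigma_mm / spacing)
    sel = mask if mask.any() else np.ones(shape, bool)
    b -= b[sel].mean()
    rms = np.sqrt((b[sel] ** 2).mean())
    return b * (amplitude / rms) if rms > 0 else b


def _corrupt(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ghosting-style artifact: shifted duplicate blended into half the slice."""
    out = values.copy()
    n0 = values.shape[0]
    shift = int(rng.integers(5, 11)) * rng.choice([-1, 1])
    half = slice(n0 // 2, None) if rng.random() < 0.5 else slice(None, n0 // 2)
    ghost = np.roll(values, shift, axis=1)
    out[half] = 0.4 * out[half] + 0.6 * ghost[half]
    # extra shear-like displaced band
    band = slice(n0 // 3, n0 // 2)
    out[band] = np.roll(out[band], -shift, axis=1)
    return out


def simulate_acquisition(volume: Volume, spec: SimulationSpec
                         ) -> tuple[list[SliceStack], GroundTruth]:
    """Simulate motion-scattered corrupted stacks from a known volume.

    The returned slices carry *nominal* (identity) transforms — recovering
    the true motion is the reconstructor's job — while the ground truth
    records the true per-slice transforms, applied scales, log bias fields
    and outlier labels ('clean', 'displaced', 'corrupted').
    """
    rng = np.random.default_rng(spec.seed)
    n_total = len(spec.orientations) * spec.slices_per_stack
    if spec.n_displaced + spec.n_corrupted > n_total:
        raise ValueError("more outlier slices requested than slices simulated")

    mean_intensity = float(volume.values.mean())
    sigma_noise = spec.noise_fraction * mean_intensity
    psf = default_psf(spec.slice_thickness, spec.inplane_spacing)

    # pass 1: clean simulation with small random motion
    stacks: list[SliceStack] = []
    true_tf: list[list[RigidTransform]] = []
    centers = []
    for s_idx, orientation in enumerate(spec.orientations):
        grids, center = _stack_geometry(volume, orientation, spec)
        centers.append(center)
        slices, tfs = [], []
        for g in grids:
            motion = _draw_motion(rng, spec, center)
            slc = Slice(np.zeros(g.shape[:2]), g, spec.slice_thickness,
                        transform=motion)
            slc.meta = {"stack": s_idx, "index": len(slices), "label": "clean"}
            slices.append(slc)
            tfs.append(motion)
        stack = SliceStack(slices, label=f"stack{s_idx}")
        for slc, y in zip(slices, simulate_slices(
                volume, build_system_matrix(stack, volume.grid, psf))):
            y = np.where(np.isfinite(y), y, 0.0)
            slc.values = y
            slc.mask = y > 0.01 * mean_intensity
        stacks.append(stack)
        true_tf.append(tfs)
    all_slices = [s for st in stacks for s in st]

    # outliers are drawn among slices with substantial head content, so that
    # every labeled outlier carries enough signal to be detectable at all
    counts = np.array([int(s.mask.sum()) for s in all_slices])
    candidates = np.flatnonzero(counts >= 0.4 * counts.max())
    n_out = spec.n_displaced + spec.n_corrupted
    if n_out > candidates.size:
        raise ValueError("not enough content-rich slices for the requested outliers")
    chosen = candidates[rng.permutation(candidates.size)[:n_out]]
    displaced = set(chosen[:spec.n_displaced].tolist())
    corrupted = set(chosen[spec.n_displaced:].tolist())

    # re-simulate displaced slices from their (grossly wrong) true pose
    for flat in sorted(displaced):
        slc = all_slices[flat]
        s_idx = slc.meta["stack"]
        disp = _draw_displacement(rng, centers[s_idx])
        slc.transform = disp.compose(slc.transform)
        true_tf[s_idx][slc.meta["index"]] = slc.transform
        one = SliceStack([slc], label="tmp")
        y = simulate_slices(volume, build_system_matrix(one, volume.grid, psf))[0]
        y = np.where(np.isfinite(y), y, 0.0)
        slc.values = y
        slc.mask = y > 0.01 * mean_intensity
        slc.meta["label"] = "displaced"
    for flat in sorted(corrupted):
        all_slices[flat].meta["label"] = "corrupted"

    # pass 2: intensity corruption, in flat slice order
    scales, biases, labels = [], [], []
    for slc in all_slices:
        y = slc.values
        if sigma_noise > 0:
            y = y + rng.normal(0.0, sigma_noise, y.shape)
        if spec.bias_amplitude > 0:
            b = _smooth_bias(rng, y.shape, spec.inplane_spacing,
                             spec.bias_sigma_mm, spec.bias_amplitude, slc.mask)
        else:
            b = np.zeros_like(y)
        s_mult = float(rng.uniform(*spec.scale_range))
        y = s_mult * np.exp(b) * y
        if slc.meta["label"] == "corrupted":
            y = _corrupt(y, rng)
        slc.values = y
        # hand the reconstructor the nominal pose
        slc.transform = RigidTransform.identity()
        scales.append(s_mult)
        biases.append(b)
        labels.append(slc.meta["label"])

    truth = GroundTruth(volume, true_tf, np.asarray(scales), biases,
                        np.asarray(labels))
    return stacks, truth
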