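"""Rigid registration by normalized mutual information.

A deterministic derivative-free pattern search over the six rigid
parameters drives both volumetric stack-to-template registration (with a
multi-start orientation sweep) and single slice-to-volume registration.
Slice registration is interleaved with reconstruction in
:func:`motion_correct`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .core import ImageGrid, RigidTransform, Slice, SliceStack, Volume
from .psf import default_psf, build_system_matrix, reconstruction_grid
from .superres import ReconSettings, reconstruct

__all__ = ["RegistrationSettings", "RegistrationError", "nmi",
           "register_stack_to_template", "register_slice_to_volume",
           "motion_correct", "MotionCorrectionResult"]


class RegistrationError(RuntimeError):
    """Raised when no admissible registration could be found."""


@dataclass
class RegistrationSettings:
    bins: int = 64
    motion_iterations: int = 9            # paper range 6-16
    min_mask_voxels: int = 50
    min_overlap: float = 0.5
    # pattern-search schedule
    init_step_mm: float = 2.0
    init_step_deg: float = 2.0
    min_step_mm: float = 0.1
    min_step_deg: float = 0.1
    max_evaluations: int = 2000
    # capture range of one slice-registration call around its start
    capture_range_mm: float = 8.0
    capture_range_deg: float = 12.0
    # lambda schedule endpoints, as factors of delta^2
    lambda_start_factor: float = 0.08
    lambda_final_factor: float = 0.01

    def __post_init__(self):
        if self.bins < 8:
            raise ValueError("need at least 8 histogram bins")
        if self.motion_iterations < 1:
            raise ValueError("motion_iterations must be >= 1")


def nmi(a: np.ndarray, b: np.ndarray, bins: int = 64,
        edges: tuple[np.ndarray, np.ndarray] | None = None) -> float:
    """Studholme normalized mutual information ``(H(A)+H(B))/H(A,B)``.

    Computed from a joint histogram over the paired samples; lies in
    [1, 2].  ``edges`` fixes the bin edges (needed for a continuous metric
    during optimization, where the overlap changes between evaluations).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("sample vectors must have equal length")
    if a.size == 0:
        raise RegistrationError("empty overlap: no paired samples")
    joint, _, _ = np.histogram2d(a, b, bins=edges if edges is not None else bins)
    n = joint.sum()
    if n == 0:
        raise RegistrationError("empty joint histogram")
    pj = joint / n

    def ent(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    h_ab = ent(pj.ravel())
    if h_ab == 0:
        return 2.0  # both images constant: degenerate, perfectly "matched"
    return (ent(pj.sum(axis=1)) + ent(pj.sum(axis=0))) / h_ab


def _pattern_search(score, params0: np.ndarray, steps0: np.ndarray,
                    steps_min: np.ndarray, max_evals: int,
                    bounds: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Maximize ``score`` by coordinate moves with step halving.

    ``bounds`` caps ``|params - params0|`` per coordinate (capture range).
    """
    params = params0.copy()
    steps = steps0.copy()
    best = score(params)
    evals = 1
    while evals < max_evals and np.any(steps > steps_min):
        improved = False
        for i in range(params.size):
            if steps[i] <= 0:
                continue
            for sgn in (1.0, -1.0):
                trial = params.copy()
                trial[i] += sgn * steps[i]
                if bounds is not None and abs(trial[i] - params0[i]) > bounds[i]:
                    continue
                val = score(trial)
                evals += 1
                if val > best + 1e-12:
                    best, params = val, trial
                    improved = True
                    break
                if evals >= max_evals:
                    break
            if evals >= max_evals:
                break
        if not improved:
            steps = steps / 2.0
    return params, best


def _sample_volume(volume: Volume, points_world: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of the volume at world points; flags in-bounds."""
    idx = volume.grid.world_to_voxel(points_world)
    inside = np.all((idx >= 0) & (idx <= np.asarray(volume.grid.shape) - 1), axis=-1)
    vals = map_coordinates(volume.values, idx.T, order=1, mode="constant", cval=0.0)
    return vals, inside


def _nmi_pv(a: np.ndarray, b: np.ndarray, lo_a, w_a, bins_a: int,
            lo_b: float, w_b: float, bins_b: int) -> float:
    """NMI from a partial-volume (bilinearly spread) joint histogram.

    Hard binning makes NMI piecewise constant below bin granularity, which
    stalls local optimizers; spreading each sample over its two nearest
    bins per axis yields a continuous metric.
    """
    fa = np.clip((a - lo_a) / w_a, 0, bins_a - 1 - 1e-9)
    fb = np.clip((b - lo_b) / w_b, 0, bins_b - 1 - 1e-9)
    ia, ib = fa.astype(int), fb.astype(int)
    da, db = fa - ia, fb - ib
    joint = np.zeros((bins_a, bins_b))
    flat = joint.ravel()
    for oa, wa in ((0, 1 - da), (1, da)):
        for ob, wb in ((0, 1 - db), (1, db)):
            np.add.at(flat, (ia + oa) * bins_b + ib + ob, wa * wb)
    pj = joint / joint.sum()

    def ent(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    h_ab = ent(pj.ravel())
    if h_ab == 0:
        return 2.0
    return (ent(pj.sum(axis=1)) + ent(pj.sum(axis=0))) / h_ab


def _adaptive_bins(n_samples: int, bins_max: int) -> int:
    # keep on the order of >= 5 samples per occupied histogram cell
    return int(np.clip(np.sqrt(n_samples / 5.0), 8, bins_max))


def _fixed_edges(a_vals: np.ndarray, b_vals: np.ndarray, bins: int):
    def edge(v):
        lo, hi = min(float(v.min()), 0.0), float(v.max())
        if hi <= lo:
            hi = lo + 1.0
        return np.linspace(lo, hi, bins + 1)
    # zero is always in range: off-grid samples land in the lowest bin
    return edge(a_vals), edge(b_vals)


def _slice_score(slc: Slice, volume: Volume, bins_max: int):
    pts_grid = slc.grid.voxel_to_world(
        np.stack([*np.meshgrid(*map(np.arange, slc.values.shape), indexing="ij"),
                  np.zeros(slc.values.shape)], axis=-1).reshape(-1, 3))
    msk = slc.mask.ravel()
    pts_grid = pts_grid[msk]
    # corrected intensities: once scales/biases are estimated, registration
    # compares model-consistent quantities (NMI absorbs what remains)
    vals = slc.corrected().ravel()[msk]
    center = pts_grid.mean(axis=0)
    bins = _adaptive_bins(vals.size, bins_max)
    vol_vals = volume.values[volume.mask] if volume.mask is not None else volume.values
    lo_a, hi_a = min(float(vals.min()), 0.0), float(vals.max())
    lo_b, hi_b = min(float(vol_vals.min()), 0.0), float(vol_vals.max())
    w_a = (hi_a - lo_a) / (bins - 1) or 1.0
    w_b = (hi_b - lo_b) / (bins - 1) or 1.0

    def score(params):
        t = RigidTransform.about_center(params, center).compose(slc.transform)
        sampled, inside = _sample_volume(volume, t.apply(pts_grid))
        if inside.sum() < max(8, 0.25 * inside.size):
            return -np.inf
        # voxels pushed off the grid sample as 0 and stay in the histogram:
        # sliding out of the volume must cost, not shrink, the overlap
        return _nmi_pv(vals, np.clip(sampled, lo_b, hi_b),
                       lo_a, w_a, bins, lo_b, w_b, bins)

    return score, center


def register_slice_to_volume(slc: Slice, volume: Volume,
                             settings: RegistrationSettings | None = None
                             ) -> RigidTransform:
    """Optimize the slice's 6-DOF pose against the current reconstruction.

    Starts from the slice's current transform; on degenerate input (too few
    in-mask voxels or constant intensities) the slice is flagged and the
    transform returned unchanged.
    """
    settings = settings or RegistrationSettings()
    n_mask = int(slc.mask.sum())
    if n_mask < settings.min_mask_voxels or np.ptp(slc.values[slc.mask]) <= 0:
        slc.meta["registration_skipped"] = True
        return slc.transform
    score, center = _slice_score(slc, volume, settings.bins)
    rad = np.radians(settings.init_step_deg)
    steps0 = np.array([rad, rad, rad] + [settings.init_step_mm] * 3)
    steps_min = np.array([np.radians(settings.min_step_deg)] * 3
                         + [settings.min_step_mm] * 3)
    bounds = np.array([np.radians(settings.capture_range_deg)] * 3
                      + [settings.capture_range_mm] * 3)
    try:
        params, best = _pattern_search(score, np.zeros(6), steps0, steps_min,
                                       settings.max_evaluations, bounds)
    except RegistrationError:
        slc.meta["registration_skipped"] = True
        return slc.transform
    if not np.isfinite(best):
        slc.meta["registration_skipped"] = True
        return slc.transform
    new = RigidTransform.about_center(params, center).compose(slc.transform)
    slc.transform = new
    slc.meta["registration_skipped"] = False
    return new


def _orientation_starts() -> list[RigidTransform]:
    """Identity plus the 24 axis-aligned rotations (with duplicates pruned)."""
    mats = []
    for perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
        P = np.eye(3)[:, list(perm)]
        for sx in (1, -1):
            for sy in (1, -1):
                for sz in (1, -1):
                    R = P @ np.diag([sx, sy, sz])
                    if np.linalg.det(R) > 0:
                        mats.append(R)
    out, seen = [], set()
    for R in mats:
        key = tuple(np.round(R.ravel()).astype(int))
        if key not in seen:
            seen.add(key)
            out.append(RigidTransform(R))
    return out


def register_stack_to_template(moving: Volume, template: Volume,
                               settings: RegistrationSettings | None = None
                               ) -> RigidTransform:
    """Multi-start volumetric rigid registration (moving -> template world).

    Starts from 24 axis-aligned orientations plus identity about the mask
    centroids, locally optimizes NMI for the most promising starts, and
    returns the best result with sufficient mask overlap.
    """
    settings = settings or RegistrationSettings()
    mmask = moving.mask if moving.mask is not None else moving.values > 0
    tmask = template.mask if template.mask is not None else template.values > 0
    if not mmask.any() or not tmask.any():
        raise RegistrationError("empty mask on moving or template volume")
    pts = moving.grid.voxel_to_world(np.argwhere(mmask))
    vals = moving.values[mmask]
    m_center = pts.mean(axis=0)
    t_center = template.grid.voxel_to_world(np.argwhere(tmask)).mean(axis=0)
    tmask_f = tmask.astype(float)
    bins = _adaptive_bins(vals.size, settings.bins)
    edges = _fixed_edges(vals, template.values[tmask], bins)

    def overlap_and_score(t: RigidTransform):
        moved = t.apply(pts)
        sampled, inside = _sample_volume(template, moved)
        idx = template.grid.world_to_voxel(moved[inside])
        in_mask = map_coordinates(tmask_f, idx.T, order=0, mode="constant") > 0
        frac = in_mask.sum() / pts.shape[0]
        if frac < settings.min_overlap:
            return frac, -np.inf
        return frac, nmi(vals[inside], sampled[inside], edges=edges)

    # rank starts: each orientation pivots about the moving centroid and
    # lands it on the template centroid
    starts = []
    for R in _orientation_starts():
        t = RigidTransform(R.rotation, t_center - R.rotation @ m_center)
        frac, sc = overlap_and_score(t)
        starts.append((sc, t))
    starts.sort(key=lambda p: -p[0])
    if not np.isfinite(starts[0][0]):
        raise RegistrationError("no orientation start reaches the minimum overlap")

    rad = np.radians(settings.init_step_deg)
    steps0 = np.array([rad] * 3 + [settings.init_step_mm] * 3)
    steps_min = np.array([np.radians(settings.min_step_deg)] * 3
                         + [settings.min_step_mm] * 3)
    best_t, best_s = None, -np.inf
    for sc, t0 in starts[:3]:
        if not np.isfinite(sc):
            continue

        def score(params, t0=t0):
            t = RigidTransform.about_center(params, t_center).compose(t0)
            return overlap_and_score(t)[1]

        params, val = _pattern_search(score, np.zeros(6), steps0, steps_min,
                                      settings.max_evaluations)
        if val > best_s:
            best_s = val
            best_t = RigidTransform.about_center(params, t_center).compose(t0)
    if best_t is None or not np.isfinite(best_s):
        raise RegistrationError("stack registration failed for all starts")
    return best_t


@dataclass
class MotionCorrectionResult:
    volume: Volume
    stacks: list[SliceStack]
    diagnostics: list = field(default_factory=list)   # ReconDiagnostics per iteration
    lambdas: list = field(default_factory=list)


def motion_correct(stacks: list[SliceStack],
                   settings: RegistrationSettings | None = None,
                   recon_settings: ReconSettings | None = None,
                   grid: ImageGrid | None = None) -> MotionCorrectionResult:
    """Interleave slice-to-volume registration with EM reconstruction.

    Per motion iteration: (skip registration on the first) -> update the
    regularization weight along a geometric schedule -> rebuild the system
    matrix -> Gaussian initialization -> EM reconstruction.  The final
    iteration runs ``em_iterations_final`` EM iterations.
    """
    settings = settings or RegistrationSettings()
    recon_settings = recon_settings or ReconSettings()
    if grid is None:
        grid = reconstruction_grid(stacks)
    n = settings.motion_iterations
    if n > 1:
        ratio = (settings.lambda_final_factor / settings.lambda_start_factor) ** (1.0 / (n - 1))
    else:
        ratio = 1.0
    result = MotionCorrectionResult(None, stacks)
    volume = None
    base_factor = recon_settings.lambda_factor
    for it in range(n):
        if it > 0:
            for st in stacks:
                for slc in st:
                    register_slice_to_volume(slc, volume, settings)
        lam_factor = settings.lambda_start_factor * ratio**it
        result.lambdas.append(lam_factor)
        rs = ReconSettings(**{**recon_settings.__dict__,
                              "lambda_factor": lam_factor})
        psfs = [default_psf(st.slices[0].thickness, st.slices[0].inplane_spacing,
                            rs.psf_truncation) for st in stacks]
        system = build_system_matrix(stacks, grid, psfs)
        n_em = rs.em_iterations_final if it == n - 1 else rs.em_iterations
        volume, diag = reconstruct(stacks, grid, rs, system=system,
                                   n_iterations=n_em)
        result.diagnostics.append(diag)
    recon_settings.lambda_factor = base_factor
    result.volume = volume
    return result
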