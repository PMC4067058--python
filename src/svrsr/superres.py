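"""Super-resolution reconstruction with EM robust statistics.

One :func:`reconstruct` call performs the inner loop of the method: Gaussian
weighted initialization, then a fixed number of EM iterations, each of which
simulates the slices, classifies voxels and slices into inliers/outliers,
refreshes scales and bias fields, and applies the robust gradient update
followed by confidence-weighted edge-preserving smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter1d

from .core import Slice, SliceStack, ImageGrid, Volume
from .intensity import BiasSettings, update_bias, update_scales
from .psf import PSFSpec, SystemMatrix, build_system_matrix, default_psf
from . import robust

__all__ = ["ReconSettings", "ReconDiagnostics", "gaussian_weighted_init",
           "regularizer_gradient", "sr_update", "reconstruct", "estimate_delta"]

_OFFSETS = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


@dataclass
class ReconSettings:
    """Knobs of the super-resolution EM loop."""

    alpha: float | None = None            # None: 0.9 / max confidence, per iteration
    lambda_factor: float = 0.02           # lambda = lambda_factor * delta^2
    delta: float | None = None            # None: from the initialization histogram
    em_iterations: int = 10
    em_iterations_final: int = 30
    use_robust: str = "em"                # "em" | "huber" | "none"
    use_intensity_matching: bool = True
    bias: BiasSettings = field(default_factory=BiasSettings)
    psf_truncation: float = 3.0
    exclusion_threshold: float = 0.5      # reporting: p_slice below => "excluded"
    inlier_init: float = 0.9              # initial mixing proportion c
    huber_factor: float = 1.35

    def __post_init__(self):
        if self.use_robust not in ("em", "huber", "none"):
            raise ValueError("use_robust must be 'em', 'huber' or 'none'")
        if self.lambda_factor < 0:
            raise ValueError("lambda_factor must be >= 0")
        if self.em_iterations < 1 or self.em_iterations_final < 1:
            raise ValueError("iteration counts must be >= 1")


@dataclass
class ReconDiagnostics:
    objective: list = field(default_factory=list)       # sum w e^2 per iteration
    data_rms: list = field(default_factory=list)
    sigma2: list = field(default_factory=list)
    c: list = field(default_factory=list)
    scales: np.ndarray | None = None
    slice_posteriors: np.ndarray | None = None
    potentials: np.ndarray | None = None
    excluded: list = field(default_factory=list)        # slice indices
    delta: float | None = None


def _flatten(stacks) -> list[Slice]:
    """Accept a stack, a list of stacks, or a flat list of slices."""
    if isinstance(stacks, SliceStack):
        return list(stacks)
    stacks = list(stacks)
    if stacks and isinstance(stacks[0], Slice):
        return stacks
    return [s for st in stacks for s in st]


def _gather(slices: Sequence[Slice], M: SystemMatrix, arrays) -> np.ndarray:
    out = np.empty(M.n_rows)
    for k in range(len(slices)):
        out[M.rows_for_slice(k)] = np.asarray(arrays[k], dtype=float).ravel()
    return out


def gaussian_weighted_init(stacks, M: SystemMatrix) -> Volume:
    """PSF-weighted average of corrected slice intensities onto the grid.

    ``x_i = sum m_ijk y*_jk / sum m_ijk`` over in-mask slice voxels; voxels
    without coverage are filled from their nearest covered voxel and left
    out of the returned volume mask.
    """
    slices = _flatten(stacks)
    ystar = _gather(slices, M, [s.corrected() for s in slices])
    valid = _gather(slices, M, [s.mask for s in slices]) > 0
    valid &= ~M.empty_rows
    num = M.adjoint(np.where(valid, ystar, 0.0))
    den = M.adjoint(valid.astype(float))
    covered = den > 0
    if not covered.any():
        raise ValueError("no slice covers the reconstruction grid")
    x = np.zeros(M.grid.shape)
    x[covered] = num[covered] / den[covered]
    if not covered.all():
        _, idx = distance_transform_edt(~covered, return_indices=True)
        x = x[tuple(idx)]
    return Volume(M.grid, x, covered)


def estimate_delta(volume: Volume) -> float:
    """Edge threshold: half the gap between the two dominant histogram modes.

    Falls back to 15% of the intensity range when fewer than two modes are
    found.
    """
    vals = volume.values[volume.mask] if volume.mask is not None else volume.values
    vals = vals[vals > 0.05 * vals.max()]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return 1.0
    counts, edges = np.histogram(vals, bins=100, range=(lo, hi))
    smooth = gaussian_filter1d(counts.astype(float), 3.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks = [i for i in range(1, 99)
             if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1]]
    if len(peaks) < 2:
        return 0.15 * (hi - lo)
    top = sorted(sorted(peaks, key=lambda i: -smooth[i])[:2])
    d = 0.5 * abs(centers[top[1]] - centers[top[0]])
    return d if d > 0 else 0.15 * (hi - lo)


def regularizer_gradient(values: np.ndarray, delta: float,
                         neighbor_weights: np.ndarray | None = None) -> np.ndarray:
    """Edge-preserving smoothing direction over the 26-neighborhood.

    ``g_i = (1/delta^2) sum_d b_id (x_{i+d} - x_i)`` with
    ``b_id = 1 / (|d| sqrt(1 + ((x_{i+d}-x_i)/(delta sqrt(|d|)))^2))``.
    This is ``-1/4`` of the true gradient of the Charbonnier-style penalty;
    the constant is absorbed into the step size, as usual.  Optional
    ``neighbor_weights`` multiply each neighbor's contribution (confidence
    weighting).  Boundary voxels use only their in-grid neighbors.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    x = np.asarray(values, dtype=float)
    xp = np.pad(x, 1, mode="edge")
    wp = None
    if neighbor_weights is not None:
        wp = np.pad(np.asarray(neighbor_weights, dtype=float), 1, mode="edge")
    g = np.zeros_like(x)
    sl = {-1: slice(0, -2), 0: slice(1, -1), 1: slice(2, None)}
    for d in _OFFSETS:
        nd = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
        nb = xp[sl[d[0]], sl[d[1]], sl[d[2]]]
        diff = nb - x
        # boundary: zero out contributions whose true neighbor is off-grid
        # (edge padding would otherwise clamp diagonals to a wrong voxel)
        for ax, da in enumerate(d):
            if da == 1:
                diff[tuple(slice(None) if a != ax else slice(-1, None)
                           for a in range(3))] = 0.0
            elif da == -1:
                diff[tuple(slice(None) if a != ax else slice(0, 1)
                           for a in range(3))] = 0.0
        b = 1.0 / (nd * np.sqrt(1.0 + (diff / (delta * np.sqrt(nd))) ** 2))
        term = b * diff
        if wp is not None:
            term = term * wp[sl[d[0]], sl[d[1]], sl[d[2]]]
        g += term
    return g / delta**2


def _row_weights(slices, M: SystemMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(p_slice * p_jk per row, validity per row)."""
    p = _gather(slices, M, [s.posteriors for s in slices])
    ps = _gather(slices, M, [np.full(s.values.shape, s.slice_posterior) for s in slices])
    valid = _gather(slices, M, [s.mask for s in slices]) > 0
    valid &= ~M.empty_rows
    w = np.where(valid, ps * p, 0.0)
    return w, valid


def sr_update(volume: Volume, stacks, M: SystemMatrix,
              settings: ReconSettings, delta: float,
              lambda_: float | None = None) -> Volume:
    """One robust gradient step plus confidence-weighted smoothing.

    ``x_i <- x_i + alpha sum_kj p_slice p_jk m_ijk e_jk`` followed by the
    edge-preserving increment with per-voxel confidence
    ``sum_kj p_slice p_jk m_ijk`` modulating each neighbor's contribution;
    voxels with zero confidence receive full (unweighted) smoothing so that
    uncovered regions are inpainted.
    """
    slices = _flatten(stacks)
    x = volume.values
    yhat = M.forward(x)
    ystar = _gather(slices, M, [s.corrected() for s in slices])
    w, valid = _row_weights(slices, M)
    e = np.where(valid, ystar - np.where(np.isfinite(yhat), yhat, 0.0), 0.0)

    conf = M.adjoint(w)
    alpha = settings.alpha
    if alpha is None:
        cmax = conf.max()
        alpha = 0.9 / cmax if cmax > 0 else 1.0
    lam = settings.lambda_factor * delta**2 if lambda_ is None else lambda_

    x_new = x + alpha * M.adjoint(w * e)
    if lam > 0:
        cmax = conf.max()
        cnorm = conf / cmax if cmax > 0 else np.zeros_like(conf)
        g_w = regularizer_gradient(x, delta, cnorm)
        g_full = regularizer_gradient(x, delta)
        reg = np.where(conf > 0, g_w, g_full)
        x_new = x_new + alpha * lam * reg
    if not np.all(np.isfinite(x_new)):
        raise FloatingPointError("non-finite values in super-resolution update")
    return Volume(volume.grid, x_new, volume.mask)


def _update_robust(slices, M, e, valid, settings, model):
    """E- and M-steps; fills slice posteriors in place.  Returns model."""
    sim_masked = e[valid]
    if settings.use_robust == "none":
        for s in slices:
            s.posteriors = np.ones(s.values.shape)
            s.slice_posterior = 1.0
        return None
    if settings.use_robust == "em":
        if model is None:
            m = robust.init_uniform_density(sim_masked)
            model = robust.VoxelRobustModel(max(float(np.mean(sim_masked**2)), 1e-12),
                                            settings.inlier_init, m)
        p_rows = np.where(valid, robust.voxel_posteriors(e, model), 0.0)
        model = robust.update_voxel_model(sim_masked,
                                          p_rows[valid], model)
    else:  # huber
        gamma = robust.huber_gamma(np.abs(sim_masked), settings.huber_factor)
        p_rows = np.where(valid, robust.huber_weights(e, gamma), 0.0)
        model = None

    pots = []
    for k, s in enumerate(slices):
        rows = M.rows_for_slice(k)
        p2d = p_rows[rows].reshape(s.values.shape)
        s.posteriors = p2d
        v2d = valid[rows].reshape(s.values.shape)
        pv = p2d[v2d]
        pots.append(float((pv * pv).sum() / pv.size) if pv.size else np.nan)
    pots = np.asarray(pots)

    if settings.use_robust == "em":
        ok = np.isfinite(pots)
        if ok.sum() >= 2:
            ps, _ = robust.slice_posteriors(pots[ok])
            full = np.zeros(len(slices))
            full[ok] = ps
        else:
            full = np.ones(len(slices))
    else:
        rms = np.array([np.sqrt(np.mean(e[M.rows_for_slice(k)][valid[M.rows_for_slice(k)]]**2))
                        if valid[M.rows_for_slice(k)].any() else np.inf
                        for k in range(len(slices))])
        full = robust.huber_slice_weights(rms, settings.huber_factor)
    for s, v, pot in zip(slices, full, pots):
        s.slice_posterior = float(v)
        s.meta["potential"] = float(pot) if np.isfinite(pot) else None
    return model


def reconstruct(stacks, grid: ImageGrid | None = None,
                settings: ReconSettings | None = None,
                system: SystemMatrix | None = None,
                psf: PSFSpec | Sequence[PSFSpec] | None = None,
                n_iterations: int | None = None,
                initial: Volume | None = None) -> tuple[Volume, ReconDiagnostics]:
    """Run the EM reconstruction loop on (pre-aligned) stacks.

    Returns the reconstructed volume and per-iteration diagnostics.  The
    system matrix is built once (or taken from ``system``) and reused for
    all EM iterations.
    """
    if isinstance(stacks, SliceStack):
        stacks = [stacks]
    settings = settings or ReconSettings()
    slices = _flatten(stacks)
    if system is None:
        if grid is None:
            raise ValueError("either a grid or a prebuilt system matrix is required")
        if psf is None:
            psf = [default_psf(st.slices[0].thickness, st.slices[0].inplane_spacing,
                               settings.psf_truncation) for st in stacks]
        system = build_system_matrix(stacks, grid, psf)
    M = system

    volume = initial if initial is not None else gaussian_weighted_init(slices, M)
    diag = ReconDiagnostics()
    delta = settings.delta if settings.delta is not None else estimate_delta(volume)
    diag.delta = delta

    n_iter = n_iterations if n_iterations is not None else settings.em_iterations
    model = None
    min_rms = np.inf
    for _ in range(n_iter):
        yhat = M.forward(volume.values)
        finite = np.isfinite(yhat)
        ystar = _gather(slices, M, [s.corrected() for s in slices])
        valid = (_gather(slices, M, [s.mask for s in slices]) > 0) & finite
        e = np.where(valid, ystar - np.where(finite, yhat, 0.0), 0.0)

        # E-step + M-step of the robust model (steps i-ii)
        model = _update_robust(slices, M, e, valid, settings, model)
        if model is not None:
            diag.sigma2.append(model.sigma2)
            diag.c.append(model.c)

        # intensity matching (step iii), then refresh corrected intensities
        if settings.use_intensity_matching:
            sim2d = M.split_rows(yhat)
            update_scales(slices, sim2d)
            update_bias(slices, sim2d, settings.bias)
            ystar = _gather(slices, M, [s.corrected() for s in slices])
            e = np.where(valid, ystar - np.where(finite, yhat, 0.0), 0.0)

        w, _ = _row_weights(slices, M)
        obj = float((w * e * e).sum())
        rms = float(np.sqrt(np.mean(e[valid] ** 2))) if valid.any() else 0.0
        diag.objective.append(obj)
        diag.data_rms.append(rms)
        min_rms = min(min_rms, rms) if rms > 0 else min_rms
        if np.isfinite(min_rms) and rms > 10.0 * min_rms:
            raise RuntimeError("reconstruction diverged: data RMS grew 10x "
                               f"from its minimum ({min_rms:.4g} -> {rms:.4g})")

        # SR update + edge-preserving smoothing (steps iv-v)
        volume = sr_update(volume, slices, M, settings, delta)

    diag.scales = np.array([s.scale for s in slices])
    diag.slice_posteriors = np.array([s.slice_posterior for s in slices])
    diag.potentials = np.array([s.meta.get("potential") if s.meta.get("potential")
                                is not None else np.nan for s in slices])
    diag.excluded = [k for k, s in enumerate(slices)
                     if s.slice_posterior < settings.exclusion_threshold]
    for k, s in enumerate(slices):
        s.excluded = k in diag.excluded
    return volume, diag
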