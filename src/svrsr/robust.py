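"""EM robust statistics for voxel and slice outlier classification.

Voxel errors are modeled as a mixture of a zero-mean Gaussian (inliers) and
a uniform density ``m`` (outliers); whole slices are classified by a
two-Gaussian mixture over their squared-posterior potentials.  A Huber
weighting alternative is provided for comparison runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VoxelRobustModel", "SliceRobustModel",
    "voxel_posteriors", "update_voxel_model", "init_uniform_density",
    "slice_potentials", "slice_posteriors",
    "huber_gamma", "huber_weights", "huber_slice_weights",
]

#: fallback reciprocal-range when all errors are identical
EPS_RANGE = 1e-6
#: relative floor on sigma to avoid posterior collapse on zero-error slices
SIGMA_MIN_REL = 1e-6


@dataclass
class VoxelRobustModel:
    """Gaussian-inlier / uniform-outlier mixture parameters."""

    sigma2: float
    c: float
    m: float

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("c must be in [0, 1]")
        if self.m <= 0:
            raise ValueError("m must be positive")


@dataclass
class SliceRobustModel:
    """Two-Gaussian mixture over slice potentials; inlier = larger mean."""

    mu_in: float
    mu_out: float
    var_in: float
    var_out: float
    prop_in: float

    @property
    def prop_out(self) -> float:
        return 1.0 - self.prop_in


def _gauss(e: np.ndarray, sigma2: float) -> np.ndarray:
    return np.exp(-0.5 * e * e / sigma2) / np.sqrt(2.0 * np.pi * sigma2)


def voxel_posteriors(errors: np.ndarray, model: VoxelRobustModel) -> np.ndarray:
    """Inlier posterior ``p = G(e) c / (G(e) c + m (1 - c))`` per voxel."""
    e = np.asarray(errors, dtype=float)
    g = _gauss(e, model.sigma2) * model.c
    return g / (g + model.m * (1.0 - model.c))


def update_voxel_model(errors: np.ndarray, posteriors: np.ndarray,
                       model: VoxelRobustModel,
                       sigma_floor: float | None = None) -> VoxelRobustModel:
    """M-step: ``sigma2 = sum p e^2 / sum p``, ``c = sum p / N``; ``m`` held."""
    e = np.asarray(errors, dtype=float).ravel()
    p = np.asarray(posteriors, dtype=float).ravel()
    sp = p.sum()
    if sp <= 0:
        raise ValueError("degenerate model: all posteriors are zero")
    sigma2 = float((p * e * e).sum() / sp)
    if sigma_floor is None:
        scale = float(np.max(np.abs(e))) or 1.0
        sigma_floor = (SIGMA_MIN_REL * scale) ** 2
    sigma2 = max(sigma2, sigma_floor)
    c = float(sp / e.size)
    return VoxelRobustModel(sigma2, min(c, 1.0), model.m)


def init_uniform_density(errors: np.ndarray) -> float:
    """Reciprocal of the error range; guarded for constant errors."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty errors")
    rng = float(e.max() - e.min())
    return 1.0 / rng if rng > 0 else 1.0 / EPS_RANGE


def log_likelihood(errors: np.ndarray, model: VoxelRobustModel) -> float:
    """Observed-data log-likelihood of the voxel mixture."""
    e = np.asarray(errors, dtype=float)
    dens = _gauss(e, model.sigma2) * model.c + model.m * (1.0 - model.c)
    return float(np.log(dens).sum())


def slice_potentials(posteriors_per_slice: list[np.ndarray]) -> np.ndarray:
    """Per-slice agreement statistic ``(sum_j p_jk^2) / N_k``."""
    out = np.empty(len(posteriors_per_slice))
    for k, p in enumerate(posteriors_per_slice):
        p = np.asarray(p, dtype=float).ravel()
        if p.size == 0:
            out[k] = np.nan
        else:
            out[k] = float((p * p).sum() / p.size)
    return out


def _gmm2_em(x: np.ndarray, max_iter: int = 50, tol: float = 1e-8,
             var_floor: float = 0.0):
    """Deterministic 1-D two-Gaussian EM, median-split initialization."""
    med = np.median(x)
    lo, hi = x <= med, x > med
    if not hi.any():  # ties at the median
        hi = x >= med
        lo = x < med
    var_floor = max(var_floor, 1e-12, 1e-6 * float(np.var(x)))

    def moments(sel):
        mu = float(x[sel].mean())
        var = max(float(np.var(x[sel])), var_floor)
        return mu, var

    mu0, var0 = moments(lo)
    mu1, var1 = moments(hi)
    w1 = float(hi.mean())
    prev_ll = -np.inf
    for _ in range(max_iter):
        g0 = (1 - w1) * _gauss(x - mu0, var0)
        g1 = w1 * _gauss(x - mu1, var1)
        tot = g0 + g1
        tot[tot <= 0] = np.finfo(float).tiny
        r1 = g1 / tot
        ll = float(np.log(tot).sum())
        w1 = float(r1.mean())
        if w1 <= 0 or w1 >= 1:
            break
        mu1 = float((r1 * x).sum() / r1.sum())
        mu0 = float(((1 - r1) * x).sum() / (1 - r1).sum())
        var1 = max(float((r1 * (x - mu1) ** 2).sum() / r1.sum()), var_floor)
        var0 = max(float(((1 - r1) * (x - mu0) ** 2).sum() / (1 - r1).sum()), var_floor)
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            break
        prev_ll = ll
    return (mu0, var0), (mu1, var1), w1


#: floor on the std of each slice-class component, on the [0, 1] potential
#: scale; prevents a razor-thin inlier mode from rejecting slightly noisier
#: but perfectly usable slices
SLICE_STD_FLOOR = 0.02


def slice_posteriors(potentials: np.ndarray,
                     std_floor: float = SLICE_STD_FLOOR
                     ) -> tuple[np.ndarray, SliceRobustModel]:
    """Slice inlier posteriors from a two-Gaussian EM over potentials.

    The component with the larger mean is the inlier class; posteriors are
    additionally made monotone non-decreasing in the potential (stronger
    agreement with the volume can never lower the inlier probability).
    Identical potentials short-circuit to all-inlier.
    """
    x = np.asarray(potentials, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 slices")
    if np.ptp(x) < 1e-12:
        model = SliceRobustModel(float(x[0]), float(x[0]), 1e-12, 1e-12, 1.0)
        return np.ones_like(x), model
    (mu0, var0), (mu1, var1), w1 = _gmm2_em(x, var_floor=std_floor**2)
    if mu1 >= mu0:
        model = SliceRobustModel(mu1, mu0, var1, var0, w1)
    else:
        model = SliceRobustModel(mu0, mu1, var0, var1, 1.0 - w1)
    g_in = model.prop_in * _gauss(x - model.mu_in, model.var_in)
    g_out = model.prop_out * _gauss(x - model.mu_out, model.var_out)
    tot = g_in + g_out
    tot[tot <= 0] = np.finfo(float).tiny
    p = g_in / tot
    order = np.argsort(x, kind="stable")
    p[order] = np.maximum.accumulate(p[order])
    return p, model


def huber_gamma(errors: np.ndarray, factor: float = 1.35) -> float:
    """Huber threshold ``gamma = 1.35 * median(|e|)`` (guarded > 0)."""
    e = np.abs(np.asarray(errors, dtype=float))
    g = factor * float(np.median(e))
    return g if g > 0 else factor * max(float(e.mean()), EPS_RANGE)


def huber_weights(errors: np.ndarray, gamma: float) -> np.ndarray:
    """``w = 1`` for ``|e| <= gamma`` else ``gamma / |e|``."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    a = np.abs(np.asarray(errors, dtype=float))
    with np.errstate(divide="ignore"):
        w = np.where(a <= gamma, 1.0, gamma / np.where(a > 0, a, 1.0))
    return w


def huber_slice_weights(slice_rms: np.ndarray, factor: float = 1.35) -> np.ndarray:
    """Huber weighting of whole slices by their RMS error (comparison mode)."""
    g = huber_gamma(slice_rms, factor)
    return huber_weights(slice_rms, g)
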