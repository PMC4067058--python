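"""Per-slice intensity matching: global scales and differential bias fields.

Scales are the weighted least-squares gain between corrected and simulated
slice intensities, renormalized so their product over all slices is one.
Bias increments are a weighted in-plane Gaussian smoothing of the log
residual, forced to zero mean per slice — constants belong to the scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import Slice

__all__ = ["BiasSettings", "update_scales", "update_bias"]


@dataclass
class BiasSettings:
    """Smoothness of the differential bias field."""

    sigma_mm: float = 12.0
    enabled: bool = True

    def __post_init__(self):
        if self.sigma_mm <= 0:
            raise ValueError("bias smoothing sigma must be positive")


def update_scales(slices: Sequence[Slice], simulated: Sequence[np.ndarray],
                  normalize: bool = True) -> np.ndarray:
    """Update every slice's scale in place and return the new scales.

    Per slice: ``s = sum p * (exp(-b) y) * yhat / sum p * (exp(-b) y)^2``
    over in-mask voxels with a valid simulation, followed by a global gauge
    fix multiplying all scales so their product equals one.
    """
    scales = np.array([s.scale for s in slices], dtype=float)
    for k, (slc, sim) in enumerate(zip(slices, simulated)):
        valid = slc.mask & np.isfinite(sim)
        if not valid.any():
            continue
        ey = np.exp(-slc.bias[valid]) * slc.values[valid]
        p = slc.posteriors[valid]
        den = float((p * ey * ey).sum())
        if den <= 0:
            continue
        num = float((p * ey * sim[valid]).sum())
        if num <= 0:  # degenerate (all-zero or anti-correlated) slice
            continue
        scales[k] = num / den
    if normalize:
        scales = scales / np.exp(np.mean(np.log(scales)))
    for slc, s in zip(slices, scales):
        slc.scale = float(s)
    return scales


def update_bias(slices: Sequence[Slice], simulated: Sequence[np.ndarray],
                settings: BiasSettings) -> None:
    """Add the smoothed weighted log-residual to each slice's bias field.

    The increment is ``conv(w * r, G) / conv(w, G)`` with ``w = y* p`` and
    ``r = log(y* / yhat)``, evaluated in-plane per slice; the updated bias
    is then recentred to zero mean over in-mask voxels.
    """
    if not settings.enabled:
        return
    for slc, sim in zip(slices, simulated):
        ystar = slc.corrected()
        valid = slc.mask & np.isfinite(sim) & (sim > 0) & (ystar > 0)
        if not valid.any():
            continue
        w = np.where(valid, ystar * slc.posteriors, 0.0)
        if w.sum() <= 0:
            continue
        r = np.zeros_like(ystar)
        r[valid] = np.log(ystar[valid] / sim[valid])
        sig_px = settings.sigma_mm / slc.inplane_spacing
        num = gaussian_filter(w * r, sig_px, mode="constant")
        den = gaussian_filter(w, sig_px, mode="constant")
        good = den > 1e-12 * w.max()
        slc.bias[good] += num[good] / den[good]
        slc.bias -= slc.bias[slc.mask].mean()
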