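"""Neighborhood gray-tone difference matrix (NGTDM) features, 5 per ROI.

For every in-mask voxel with at least one in-mask 26-neighbor, the absolute
difference between its level and the mean level of those neighbors is
accumulated per gray level: ``s_i = Σ |i − Ā|`` over voxels of level i,
with ``n_i`` the voxel count and ``p_i = n_i / N``.

Coarseness = 1 / Σ p_i s_i is an inverse measure of the local rate of
intensity change: high coarseness means locally uniform texture. A fully
uniform ROI has Σ p_i s_i = 0; coarseness is then the documented sentinel
``COARSENESS_SENTINEL`` (1e6).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .discretize import DiscretizedROI

NGTDM_NAMES = ["coarseness", "contrast", "busyness", "complexity", "strength"]

COARSENESS_SENTINEL = 1.0e6

_KERNEL = np.ones((3, 3, 3))
_KERNEL[1, 1, 1] = 0.0


def ngtdm_matrix(d: DiscretizedROI) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(s, n)``: per-level summed differences and voxel counts.

    Both arrays are indexed by level-1 (length ``n_levels``). Only voxels
    with at least one in-mask neighbor contribute.
    """
    d = d.cropped()
    m = d.mask.astype(float)
    lev = d.levels.astype(float)
    nb_sum = ndi.convolve(lev * m, _KERNEL, mode="constant", cval=0.0)
    nb_cnt = ndi.convolve(m, _KERNEL, mode="constant", cval=0.0)
    valid = d.mask & (nb_cnt > 0.5)
    a_mean = np.zeros_like(lev)
    a_mean[valid] = nb_sum[valid] / nb_cnt[valid]
    diffs = np.abs(lev - a_mean)[valid]
    levels = d.levels[valid]
    s = np.zeros(d.n_levels)
    np.add.at(s, levels - 1, diffs)
    n = np.bincount(levels - 1, minlength=d.n_levels).astype(float)
    return s, n


def ngtdm_features(d: DiscretizedROI) -> dict:
    s, n = ngtdm_matrix(d)
    N = n.sum()
    if N == 0:
        raise ValueError("NGTDM requires a nonempty mask with valid neighborhoods")
    p = n / N
    present = p > 0
    ngp = int(present.sum())
    i = np.arange(1, d.n_levels + 1, dtype=float)

    psi = float(p @ s)
    coarseness = 1.0 / psi if psi > 0 else COARSENESS_SENTINEL

    if ngp > 1:
        ip, pp, sp = i[present], p[present], s[present]
        dij2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = float((np.outer(pp, pp) * dij2).sum() / (ngp * (ngp - 1)) * (s.sum() / N))
        den_bus = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = psi / den_bus if den_bus > 0 else 0.0
        num = np.abs(ip[:, None] - ip[None, :]) * (
            (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
            / (pp[:, None] + pp[None, :]))
        complexity = float(num.sum() / N)
        strength = (float(((pp[:, None] + pp[None, :]) * dij2).sum()) / s.sum()
                    if s.sum() > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }
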