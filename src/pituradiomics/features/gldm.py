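"""Gray-level dependence matrix (GLDM) features, 14 per ROI.

The dependence of a voxel is the number of its in-mask 26-neighbors whose
gray level differs from the center's by at most ``alpha`` (default 0). The
matrix ``P[i-1, d]`` counts voxels by (gray level, dependence); every
in-mask voxel contributes exactly once, so ΣP equals the voxel count.
"""

from __future__ import annotations

import numpy as np

from ._directions import OFFSETS_26, shifted_views
from .discretize import DiscretizedROI

GLDM_NAMES = [
    "small_dependence_emphasis", "large_dependence_emphasis",
    "gray_level_nonuniformity", "dependence_nonuniformity",
    "dependence_nonuniformity_normalized", "gray_level_variance",
    "dependence_variance", "dependence_entropy",
    "low_gray_level_emphasis", "high_gray_level_emphasis",
    "small_dependence_low_gray_level_emphasis",
    "small_dependence_high_gray_level_emphasis",
    "large_dependence_low_gray_level_emphasis",
    "large_dependence_high_gray_level_emphasis",
]


def gldm_matrix(d: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix ``P[i-1, dep]``, dep in 0..26."""
    d = d.cropped()
    if d.n_voxels == 0:
        raise ValueError("GLDM requires a nonempty mask")
    dep = np.zeros(d.levels.shape, dtype=np.int32)
    for off in OFFSETS_26:
        lev_c, lev_n = shifted_views(d.levels, off)
        ok = (lev_c > 0) & (lev_n > 0) & (np.abs(lev_c - lev_n) <= alpha)
        c_view, _ = shifted_views(dep, off)
        c_view += ok
    i = d.levels[d.mask] - 1
    j = dep[d.mask]
    P = np.zeros((d.n_levels, 27))
    np.add.at(P, (i, j), 1.0)
    return P


def gldm_features(d: DiscretizedROI, alpha: int = 0) -> dict:
    P = gldm_matrix(d, alpha)
    nz = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    j = np.arange(1, P.shape[1] + 1, dtype=float)  # dependence d maps to column d+1
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    p = P / nz
    mu_i = float(i @ (pi / nz))
    mu_j = float(j @ (pj / nz))
    pr = p[p > 0]
    return {
        "small_dependence_emphasis": float((pj / j**2).sum() / nz),
        "large_dependence_emphasis": float((pj * j**2).sum() / nz),
        "gray_level_nonuniformity": float((pi**2).sum() / nz),
        "dependence_nonuniformity": float((pj**2).sum() / nz),
        "dependence_nonuniformity_normalized": float((pj**2).sum() / nz**2),
        "gray_level_variance": float(((i - mu_i) ** 2) @ (pi / nz)),
        "dependence_variance": float(((j - mu_j) ** 2) @ (pj / nz)),
        "dependence_entropy": float(-(pr * np.log2(pr)).sum()),
        "low_gray_level_emphasis": float((pi / i**2).sum() / nz),
        "high_gray_level_emphasis": float((pi * i**2).sum() / nz),
        "small_dependence_low_gray_level_emphasis":
            float((P / np.outer(i**2, j**2)).sum() / nz),
        "small_dependence_high_gray_level_emphasis":
            float((P * np.outer(i**2, 1.0 / j**2)).sum() / nz),
        "large_dependence_low_gray_level_emphasis":
            float((P * np.outer(1.0 / i**2, j**2)).sum() / nz),
        "large_dependence_high_gray_level_emphasis":
            float((P * np.outer(i**2, j**2)).sum() / nz),
    }
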