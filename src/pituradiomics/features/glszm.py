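"""Gray-level size-zone matrix (GLSZM) features, 16 per ROI.

A zone is a 26-connected component of equal-level in-mask voxels; the
matrix counts zones by (gray level, zone size). Direction-free by
construction (a single matrix per ROI).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .discretize import DiscretizedROI

GLSZM_NAMES = [
    "small_area_emphasis", "large_area_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "size_zone_nonuniformity",
    "size_zone_nonuniformity_normalized", "zone_percentage",
    "gray_level_variance", "zone_variance", "zone_entropy",
    "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis", "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis", "large_area_high_gray_level_emphasis",
]

_STRUCT = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(d: DiscretizedROI) -> np.ndarray:
    """Zone count matrix ``P[i-1, s-1]`` (gray level × zone size)."""
    d = d.cropped()
    n_vox = d.n_voxels
    if n_vox == 0:
        raise ValueError("GLSZM requires a nonempty mask")
    P = np.zeros((d.n_levels, n_vox))
    for level in np.unique(d.in_mask_levels):
        labels, n = ndi.label(d.levels == level, structure=_STRUCT)
        if n:
            sizes = np.bincount(labels.ravel())[1:]
            np.add.at(P, (level - 1, sizes - 1), 1.0)
    return P


def glszm_features(d: DiscretizedROI) -> dict:
    n_vox = d.n_voxels
    P = glszm_matrix(d)
    nz = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    s = np.arange(1, P.shape[1] + 1, dtype=float)
    pi = P.sum(axis=1)
    ps = P.sum(axis=0)
    p = P / nz
    mu_i = float(i @ (pi / nz))
    mu_s = float(s @ (ps / nz))
    pr = p[p > 0]
    return {
        "small_area_emphasis": float((ps / s**2).sum() / nz),
        "large_area_emphasis": float((ps * s**2).sum() / nz),
        "gray_level_nonuniformity": float((pi**2).sum() / nz),
        "gray_level_nonuniformity_normalized": float((pi**2).sum() / nz**2),
        "size_zone_nonuniformity": float((ps**2).sum() / nz),
        "size_zone_nonuniformity_normalized": float((ps**2).sum() / nz**2),
        "zone_percentage": float(nz / n_vox),
        "gray_level_variance": float(((i - mu_i) ** 2) @ (pi / nz)),
        "zone_variance": float(((s - mu_s) ** 2) @ (ps / nz)),
        "zone_entropy": float(-(pr * np.log2(pr)).sum()),
        "low_gray_level_zone_emphasis": float((pi / i**2).sum() / nz),
        "high_gray_level_zone_emphasis": float((pi * i**2).sum() / nz),
        "small_area_low_gray_level_emphasis":
            float((P / np.outer(i**2, s**2)).sum() / nz),
        "small_area_high_gray_level_emphasis":
            float((P * np.outer(i**2, 1.0 / s**2)).sum() / nz),
        "large_area_low_gray_level_emphasis":
            float((P * np.outer(1.0 / i**2, s**2)).sum() / nz),
        "large_area_high_gray_level_emphasis":
            float((P * np.outer(i**2, s**2)).sum() / nz),
    }
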