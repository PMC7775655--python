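"""Gray-level run-length matrix (GLRLM) features, 16 per ROI.

Runs are maximal straight segments of equal gray level along one of the 13
unique 3D directions; out-of-mask voxels break runs. Features are computed
per direction and averaged.
"""

from __future__ import annotations

import numpy as np

from ._directions import DIRECTIONS_13
from .discretize import DiscretizedROI

GLRLM_NAMES = [
    "short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "run_length_nonuniformity",
    "run_length_nonuniformity_normalized", "run_percentage",
    "gray_level_variance", "run_variance", "run_entropy",
    "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis",
]


def glrlm_matrix(d: DiscretizedROI, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length count matrix ``P[i-1, r-1]`` for one direction.

    Voxels are sorted into lines via the cross-product line invariant; runs
    are contiguous same-level stretches of in-mask voxels within a line.
    """
    shape = d.levels.shape
    X, Y, Z = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    x, y, z = X.ravel(), Y.ravel(), Z.ravel()
    lev = d.levels.ravel()
    dx, dy, dz = direction
    t = x * dx + y * dy + z * dz
    k1 = y * dz - z * dy
    k2 = z * dx - x * dz
    k3 = x * dy - y * dx
    order = np.lexsort((t, k1, k2, k3))
    lev_s = lev[order]
    line = np.stack([k1[order], k2[order], k3[order]], axis=1)
    new_line = np.any(line[1:] != line[:-1], axis=1)
    new_run = np.concatenate(([True], new_line | (lev_s[1:] != lev_s[:-1])))
    run_id = np.cumsum(new_run) - 1
    run_len = np.bincount(run_id)
    run_lev = lev_s[new_run]
    keep = run_lev > 0
    run_len, run_lev = run_len[keep], run_lev[keep]
    rmax = max(shape)
    P = np.zeros((d.n_levels, rmax))
    np.add.at(P, (run_lev - 1, run_len - 1), 1.0)
    return P


def _features_one(P: np.ndarray, n_voxels: int) -> dict:
    nr = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    j = np.arange(1, P.shape[1] + 1, dtype=float)
    pi = P.sum(axis=1)   # per gray level
    pj = P.sum(axis=0)   # per run length
    p = P / nr
    mu_i = float(i @ pi.__truediv__(nr))
    mu_j = float(j @ pj.__truediv__(nr))
    pr = p[p > 0]
    return {
        "short_run_emphasis": float((pj / j**2).sum() / nr),
        "long_run_emphasis": float((pj * j**2).sum() / nr),
        "gray_level_nonuniformity": float((pi**2).sum() / nr),
        "gray_level_nonuniformity_normalized": float((pi**2).sum() / nr**2),
        "run_length_nonuniformity": float((pj**2).sum() / nr),
        "run_length_nonuniformity_normalized": float((pj**2).sum() / nr**2),
        "run_percentage": float(nr / n_voxels),
        "gray_level_variance": float(((i - mu_i) ** 2) @ (pi / nr)),
        "run_variance": float(((j - mu_j) ** 2) @ (pj / nr)),
        "run_entropy": float(-(pr * np.log2(pr)).sum()),
        "low_gray_level_run_emphasis": float((pi / i**2).sum() / nr),
        "high_gray_level_run_emphasis": float((pi * i**2).sum() / nr),
        "short_run_low_gray_level_emphasis":
            float((P / np.outer(i**2, j**2)).sum() / nr),
        "short_run_high_gray_level_emphasis":
            float((P * np.outer(i**2, 1.0 / j**2)).sum() / nr),
        "long_run_low_gray_level_emphasis":
            float((P * np.outer(1.0 / i**2, j**2)).sum() / nr),
        "long_run_high_gray_level_emphasis":
            float((P * np.outer(i**2, j**2)).sum() / nr),
    }


def glrlm_features(d: DiscretizedROI) -> dict:
    d = d.cropped()
    n_vox = d.n_voxels
    if n_vox == 0:
        raise ValueError("GLRLM requires a nonempty mask")
    feats = {k: 0.0 for k in GLRLM_NAMES}
    for direction in DIRECTIONS_13:
        f = _features_one(glrlm_matrix(d, direction), n_vox)
        for k in GLRLM_NAMES:
            feats[k] += f[k]
    return {k: v / len(DIRECTIONS_13) for k, v in feats.items()}
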