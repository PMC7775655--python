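"""Gray-level co-occurrence matrix (GLCM) features, 24 per ROI.

One symmetric, normalized co-occurrence matrix is built per direction
(distance 1, the 13 unique 3D directions, both in-mask voxels required);
features are computed per direction and averaged. Logs are base 2.

Degenerate conventions (documented and tested): with a single gray level
present, HX = HY = 0 and IMC1 is defined as 0, IMC2 as 0, correlation as 1,
MCC as 1. A single-voxel ROI has no voxel pairs and raises.
"""

from __future__ import annotations

import numpy as np

from ._directions import DIRECTIONS_13, shifted_views
from .discretize import DiscretizedROI

GLCM_NAMES = [
    "autocorrelation", "cluster_prominence", "cluster_shade", "cluster_tendency",
    "contrast", "correlation", "difference_average", "difference_entropy",
    "difference_variance", "inverse_difference", "inverse_difference_moment",
    "inverse_difference_moment_normalized", "inverse_difference_normalized",
    "informational_measure_of_correlation_1", "informational_measure_of_correlation_2",
    "inverse_variance", "joint_average", "joint_energy", "joint_entropy",
    "maximal_correlation_coefficient", "maximum_probability", "sum_average",
    "sum_entropy", "sum_squares",
]

_EPS = np.finfo(float).tiny


def glcm_matrix(d: DiscretizedROI, direction: tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one direction (unnormalized)."""
    ng = d.n_levels
    lev_c, lev_n = shifted_views(d.levels, direction)
    valid = (lev_c > 0) & (lev_n > 0)
    i, j = lev_c[valid] - 1, lev_n[valid] - 1
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(float)
    return counts + counts.T


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _features_one(P: np.ndarray) -> dict:
    """Feature set from one normalized symmetric co-occurrence matrix."""
    ng = P.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float(i @ px)
    muy = float(i @ py)
    sigx = float(np.sqrt(((i - mux) ** 2) @ px))
    sigy = float(np.sqrt(((i - muy) ** 2) @ py))
    ii, jj = np.meshgrid(i, i, indexing="ij")

    k_diff = np.arange(ng, dtype=float)           # |i-j| = 0..ng-1
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), P)
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)  # i+j = 2..2ng
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int) - 2, P)

    hx, hy = _entropy(px), _entropy(py)
    hxy = _entropy(P.ravel())
    outer = np.outer(px, py)
    nz = (P > 0) & (outer > 0)
    hxy1 = float(-(P[nz] * np.log2(outer[nz])).sum())
    pos = outer > 0
    hxy2 = float(-(outer[pos] * np.log2(outer[pos])).sum())

    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    corr = ((float((ii * jj * P).sum()) - mux * muy) / (sigx * sigy)
            if sigx > 0 and sigy > 0 else 1.0)

    # maximal correlation coefficient: sqrt of 2nd-largest eigenvalue of Q
    present = px > 0
    if present.sum() > 1:
        Pp = P[np.ix_(present, present)]
        pxp, pyp = px[present], py[present]
        Q = (Pp / pxp[:, None]) @ (Pp / pyp[:, None]).T
        eig = np.sort(np.abs(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(np.clip(eig[-2], 0.0, 1.0)))
    else:
        mcc = 1.0

    da = float(k_diff @ p_diff)
    off = ii != jj
    return {
        "autocorrelation": float((ii * jj * P).sum()),
        "cluster_prominence": float((((ii + jj) - mux - muy) ** 4 * P).sum()),
        "cluster_shade": float((((ii + jj) - mux - muy) ** 3 * P).sum()),
        "cluster_tendency": float((((ii + jj) - mux - muy) ** 2 * P).sum()),
        "contrast": float(((ii - jj) ** 2 * P).sum()),
        "correlation": corr,
        "difference_average": da,
        "difference_entropy": _entropy(p_diff),
        "difference_variance": float(((k_diff - da) ** 2) @ p_diff),
        "inverse_difference": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "inverse_difference_moment": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "inverse_difference_moment_normalized":
            float((P / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "inverse_difference_normalized":
            float((P / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "informational_measure_of_correlation_1": imc1,
        "informational_measure_of_correlation_2": imc2,
        "inverse_variance": float((P[off] / (ii[off] - jj[off]) ** 2).sum()),
        "joint_average": mux,
        "joint_energy": float((P**2).sum()),
        "joint_entropy": hxy,
        "maximal_correlation_coefficient": mcc,
        "maximum_probability": float(P.max()),
        "sum_average": float(k_sum @ p_sum),
        "sum_entropy": _entropy(p_sum),
        "sum_squares": float(((i - mux) ** 2) @ px),
    }


def glcm_features(d: DiscretizedROI) -> dict:
    """Direction-averaged GLCM feature set."""
    d = d.cropped()
    feats: dict[str, float] = {k: 0.0 for k in GLCM_NAMES}
    n_used = 0
    for direction in DIRECTIONS_13:
        C = glcm_matrix(d, direction)
        total = C.sum()
        if total == 0:
            continue  # no in-mask pairs along this direction
        f = _features_one(C / total)
        for k in GLCM_NAMES:
            feats[k] += f[k]
        n_used += 1
    if n_used == 0:
        raise ValueError("GLCM undefined: ROI has no in-mask voxel pairs")
    return {k: v / n_used for k, v in feats.items()}
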