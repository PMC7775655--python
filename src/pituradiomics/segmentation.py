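"""Pre-processing and tumor segmentation chain.

The chain mirrors a semi-automatic clinical workflow: resample to isotropic
voxels, z-normalize intensities inside the lesion region, run slice-wise
fuzzy c-means (FCM) clustering inside an operator-placed rectangle, clean
the 3D mask (largest connected component + hole filling), transfer it onto
the second contrast by an affine transform with linear interpolation, and
derive boundary-eroded ROI variants (0.25 and 0.5 cm shells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .volume import SLICE_AXIS, BoundingROI, ImageVolume, LesionMask

# 26-connectivity for 3D component labeling
_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# resampling and normalization
# ---------------------------------------------------------------------------

def resample_isotropic(vol: ImageVolume, target_mm: float | None = None) -> ImageVolume:
    """Resample to isotropic spacing by trilinear interpolation.

    ``target_mm`` defaults to the minimum input spacing, so no axis is
    downsampled. The grid origin is preserved; the world extent changes by
    less than one voxel.
    """
    if target_mm is None:
        target_mm = min(vol.spacing)
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    old_sp = np.asarray(vol.spacing)
    new_shape = np.maximum(np.round((np.asarray(vol.shape) - 1) * old_sp / target_mm) + 1, 2)
    new_shape = new_shape.astype(int)
    coords = np.meshgrid(
        *[np.arange(n) * target_mm / s for n, s in zip(new_shape, old_sp)],
        indexing="ij",
    )
    data = ndi.map_coordinates(vol.data, np.stack(coords), order=1, mode="nearest")
    return ImageVolume(data, (target_mm,) * 3, vol.modality)


def resample_mask(mask: LesionMask, target_mm: float) -> LesionMask:
    """Nearest-equivalent mask resampling: trilinear on {0,1} then >= 0.5."""
    as_vol = ImageVolume(mask.data.astype(float), mask.spacing)
    res = resample_isotropic(as_vol, target_mm)
    return LesionMask(res.data >= 0.5, res.spacing, mask.variant)


def normalize_roi(vol: ImageVolume, mask: LesionMask) -> ImageVolume:
    """Affine intensity transform making the in-mask mean 0 and SD 1.

    The population (n-denominator) SD is used. The same affine map is
    applied to the whole volume, so relative contrast outside the ROI is
    preserved.
    """
    vals = vol.data[mask.data]
    if vals.size < 2:
        raise ValueError("normalize_roi requires a mask with at least 2 voxels")
    mu, sd = float(vals.mean()), float(vals.std())  # ddof=0
    if sd == 0:
        raise ValueError(f"zero intensity variance inside ROI ({vol.modality}); cannot normalize")
    return vol.with_data((vol.data - mu) / sd)


# ---------------------------------------------------------------------------
# fuzzy c-means
# ---------------------------------------------------------------------------

@dataclass
class FCMResult:
    membership: np.ndarray      # (k, n) fuzzy memberships, columns sum to 1
    centroids: np.ndarray       # (k,) cluster centers
    objective_history: list     # J_m per iteration, non-increasing
    converged: bool


def fuzzy_cmeans_1d(values: np.ndarray, n_clusters: int = 2, m: float = 2.0,
                    tol: float = 1e-5, max_iter: int = 300,
                    seed: int | np.random.Generator = 0) -> FCMResult:
    """Fuzzy c-means on scalar intensities.

    Minimizes J_m = Σ_i Σ_k u_ik^m |x_i − v_k|² by alternating membership and
    centroid updates. Centroids are initialized k-means++-style on the
    distinct values. Convergence is declared when the objective improves by
    less than ``tol`` (relative to its initial value).
    """
    x = np.asarray(values, dtype=float).ravel()
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    uniq = np.unique(x)
    if uniq.size < n_clusters:
        raise ValueError(
            f"need at least {n_clusters} distinct intensities, got {uniq.size}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # k-means++-style init on the distinct values
    centroids = [uniq[rng.integers(uniq.size)]]
    for _ in range(1, n_clusters):
        d2 = np.min([(uniq - c) ** 2 for c in centroids], axis=0)
        if d2.sum() == 0:
            centroids.append(uniq[rng.integers(uniq.size)])
        else:
            centroids.append(rng.choice(uniq, p=d2 / d2.sum()))
    v = np.sort(np.asarray(centroids, dtype=float))

    expo = 2.0 / (m - 1.0)
    history: list[float] = []
    converged = False
    u = None
    for _ in range(max_iter):
        d2 = (x[None, :] - v[:, None]) ** 2  # (k, n)
        zero = d2 < 1e-300
        if zero.any():
            u = np.where(zero, 1.0, 0.0)
            col = zero.any(axis=0)
            u[:, col] /= u[:, col].sum(axis=0)
            inv = (d2[:, ~col]) ** (-1.0 / (m - 1.0) * 1.0)
            u[:, ~col] = inv / inv.sum(axis=0)
        else:
            inv = d2 ** (-1.0 / (m - 1.0))
            u = inv / inv.sum(axis=0)
        um = u ** m
        j = float((um * d2).sum())
        v = (um @ x) / um.sum(axis=1)
        history.append(j)
        if len(history) > 1 and history[-2] - history[-1] < tol * max(history[0], 1.0):
            converged = True
            break
    return FCMResult(u, v, history, converged)


def fcm_segment(vol: ImageVolume, roi: BoundingROI, n_clusters: int = 2,
                m: float = 2.0, tol: float = 1e-5, max_iter: int = 300,
                seed: int = 0) -> LesionMask:
    """Slice-wise FCM segmentation inside the operator rectangle.

    Each slice in the ROI's slice range is clustered independently; the
    lesion cluster is the one with the highest centroid (the enhancing
    tissue on contrast-enhanced T1). A warning is emitted (and the best
    iterate kept) if any slice fails to converge within ``max_iter``.
    """
    roi.validate(vol.shape)
    r0, r1, c0, c1 = roi.rect
    s0, s1 = roi.slice_range
    raw = np.zeros(vol.shape, dtype=bool)
    ss = np.random.SeedSequence(seed).spawn(s1 - s0)
    for k, z in enumerate(range(s0, s1)):
        patch = vol.data[r0:r1, c0:c1, z]
        res = fuzzy_cmeans_1d(patch.ravel(), n_clusters, m, tol, max_iter,
                              np.random.default_rng(ss[k]))
        if not res.converged:
            warnings.warn(f"FCM did not converge on slice {z}; using best iterate",
                          stacklevel=2)
        lesion_cluster = int(np.argmax(res.centroids))
        assign = np.argmax(res.membership, axis=0).reshape(patch.shape)
        raw[r0:r1, c0:c1, z] = assign == lesion_cluster
    return LesionMask(raw, vol.spacing, "original")


# ---------------------------------------------------------------------------
# mask cleanup and geometry
# ---------------------------------------------------------------------------

def postprocess_mask(raw: LesionMask) -> LesionMask:
    """Keep the largest 26-connected 3D component and fill internal holes.

    Holes are filled slice-wise in 2D first (cavities open along the slice
    axis) and then in 3D, so the result contains no enclosed background.
    """
    if raw.n_voxels == 0:
        raise ValueError("cannot post-process an empty mask")
    labels, n = ndi.label(raw.data, structure=_STRUCT_3D)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        keep = labels == int(np.argmax(counts))
    else:
        keep = raw.data.copy()
    for z in range(keep.shape[SLICE_AXIS]):
        keep[:, :, z] = ndi.binary_fill_holes(keep[:, :, z])
    keep = ndi.binary_fill_holes(keep)
    return LesionMask(keep, raw.spacing, raw.variant)


def transfer_mask(mask: LesionMask, affine: np.ndarray, target: ImageVolume,
                  threshold: float = 0.5) -> LesionMask:
    """Resample a mask onto another grid through an affine transform.

    ``affine`` is the 4x4 voxel-to-voxel map from target coordinates to
    source (mask) coordinates. The binary mask is interpolated linearly as a
    continuous field and re-binarized at ``threshold``; with the identity
    transform on the same grid the input is returned exactly.
    """
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine must be an invertible 4x4 matrix")
    field = ndi.affine_transform(
        mask.data.astype(float), affine[:3, :3], offset=affine[:3, 3],
        output_shape=target.shape, order=1, mode="constant", cval=0.0)
    return LesionMask(field >= threshold, target.spacing, mask.variant)


_DEPTH_VARIANTS = {0.25: "eroded_025", 0.5: "eroded_05"}


def erode_shell(mask: LesionMask, depth_cm: float) -> LesionMask:
    """Remove the boundary shell of physical depth ``depth_cm`` from a mask.

    Spacing-aware binary erosion through the 3D Euclidean distance
    transform: a voxel survives iff its distance to the mask boundary is at
    least ``depth_cm`` (given in cm, converted to mm). Depth 0 is the
    identity; eroding a lesion away entirely raises.
    """
    if mask.n_voxels == 0:
        raise ValueError("cannot erode an empty mask")
    if depth_cm < 0:
        raise ValueError("erosion depth must be non-negative")
    depth_mm = depth_cm * 10.0
    if depth_mm == 0:
        return replace(mask)
    dist = ndi.distance_transform_edt(mask.data, sampling=mask.spacing)
    out = dist >= depth_mm
    if not out.any():
        raise ValueError(
            f"{depth_cm} cm erosion removed the whole lesion; use the original mask variant")
    variant = _DEPTH_VARIANTS.get(depth_cm, mask.variant)
    return LesionMask(out, mask.spacing, variant)


def segment_case(t1ce: ImageVolume, t2: ImageVolume, roi: BoundingROI | None = None,
                 truth_hint: LesionMask | None = None, target_mm: float | None = None,
                 n_clusters: int = 2, m: float = 2.0, tol: float = 1e-5,
                 max_iter: int = 300, seed: int = 0,
                 mask_override: LesionMask | None = None):
    """Full per-case chain: resample both channels, segment on T1CE, clean,
    transfer to T2 (shared grid after isotropic resampling, identity affine).

    Returns ``(t1ce_iso_norm, t2_iso_norm, mask)``. ``roi`` may be supplied
    directly or derived from ``truth_hint`` (the operator's rectangle around
    the visible lesion). ``mask_override`` replaces the automatic
    segmentation (the manual-correction hook) but still goes through
    post-processing.
    """
    if target_mm is None:
        target_mm = min(min(t1ce.spacing), min(t2.spacing))
    t1_iso = resample_isotropic(t1ce, target_mm)
    t2_iso = resample_isotropic(t2, target_mm)
    if mask_override is not None:
        raw = resample_mask(mask_override, target_mm)
    else:
        if roi is None:
            if truth_hint is None:
                raise ValueError("segment_case needs an ROI, a truth hint, or a mask override")
            roi = BoundingROI.around_mask(resample_mask(truth_hint, target_mm), pad=3)
        raw = fcm_segment(t1_iso, roi, n_clusters, m, tol, max_iter, seed)
    mask = postprocess_mask(raw)
    mask = transfer_mask(mask, np.eye(4), t2_iso)  # shared grid: identity transfer
    t1_norm = normalize_roi(t1_iso, mask)
    t2_norm = normalize_roi(t2_iso, mask)
    return t1_norm, t2_norm, mask
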