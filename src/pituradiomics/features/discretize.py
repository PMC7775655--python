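"""Gray-level discretization of a masked ROI."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..volume import ImageVolume, LesionMask


@dataclass
class DiscretizedROI:
    """Integer gray-level grid within a mask.

    ``levels`` holds values in ``[1, n_levels]`` inside the mask and 0
    outside. ``spacing`` is carried along for neighborhood-aware families.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_edges: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = "T1CE"
    variant: str = "original"

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def cropped(self, pad: int = 1) -> "DiscretizedROI":
        """Restrict the grid to the mask bounding box (+``pad``), for speed."""
        idx = np.argwhere(self.mask)
        lo = np.maximum(idx.min(axis=0) - pad, 0)
        hi = np.minimum(idx.max(axis=0) + 1 + pad, self.mask.shape)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        return DiscretizedROI(self.levels[sl], self.mask[sl], self.n_levels,
                              self.bin_edges, self.spacing, self.modality, self.variant)


def discretize(vol: ImageVolume, mask: LesionMask, n_bins: int = 32) -> DiscretizedROI:
    """Equal-width binning of in-mask intensities into ``n_bins`` levels.

    The in-mask minimum maps to level 1 and the maximum to level
    ``n_bins``. A constant ROI collapses to a single level (with a warning);
    downstream texture features then use their degenerate conventions.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    m = mask.data
    if not m.any():
        raise ValueError("cannot discretize an empty mask")
    vals = vol.data[m]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(vol.shape, dtype=np.int32)
    if hi == lo:
        warnings.warn("constant ROI: all voxels assigned gray level 1", stacklevel=2)
        levels[m] = 1
        edges = np.array([lo, hi])
    else:
        width = (hi - lo) / n_bins
        lv = np.floor((vals - lo) / width).astype(np.int32) + 1
        levels[m] = np.clip(lv, 1, n_bins)
        edges = lo + width * np.arange(n_bins + 1)
    return DiscretizedROI(levels, m, n_bins, edges, mask.spacing,
                          vol.modality, mask.variant)
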