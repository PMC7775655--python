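"""Core image containers: 3D intensity volumes, binary lesion masks, operator ROIs.

Arrays are indexed ``[row, col, slice]``: the last axis is the slice (stack)
axis, matching the coronal acquisition geometry in which in-plane resolution
is finer than the slice spacing. ``voxel_spacing_mm`` follows the same axis
order and may be anisotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

#: axis along which 2D slices are stacked
SLICE_AXIS = 2

MASK_VARIANTS = ("original", "eroded_025", "eroded_05")


def _spacing_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    data
        3D float array of intensities.
    spacing
        Voxel edge lengths in mm, one per axis; strictly positive.
    modality
        ``"T1CE"`` (contrast-enhanced T1-weighted) or ``"T2"`` (T2-weighted).
    affine
        4x4 grid-to-world transform. Defaults to a diagonal scaling by
        ``spacing`` (axis-aligned grid at the world origin).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = "T1CE"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if self.data.size == 0:
            raise ValueError("empty volume")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if self.modality not in ("T1CE", "T2"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.affine is None:
            self.affine = _spacing_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def load(cls, path, modality: str = "T1CE") -> "ImageVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing, modality, img.affine)


@dataclass
class LesionMask:
    """Binary 3D tumor mask aligned to an :class:`ImageVolume` grid.

    ``variant`` records which ROI definition the mask represents: the
    original segmentation or one of the two boundary-eroded shells used to
    exclude possibly non-tumorous edge voxels.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    variant: str = "original"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.variant not in MASK_VARIANTS:
            raise ValueError(f"variant must be one of {MASK_VARIANTS}, got {self.variant!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing))

    def save(self, path) -> None:
        aff = _spacing_affine(self.spacing)
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), aff), str(path))

    @classmethod
    def load(cls, path, variant: str = "original") -> "LesionMask":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj) > 0, spacing, variant)


@dataclass
class BoundingROI:
    """Operator-placed rectangular region plus begin/end slice indices.

    Emulates the initial rectangle the operator draws around the lesion and
    the first/last slice containing it; segmentation runs only inside it.
    Bounds are half-open, ``rect = (row0, row1, col0, col1)``.
    """

    rect: tuple[int, int, int, int]
    slice_range: tuple[int, int]

    def validate(self, shape: tuple[int, int, int]) -> None:
        r0, r1, c0, c1 = self.rect
        s0, s1 = self.slice_range
        if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
            raise ValueError(f"rectangle {self.rect} empty or outside grid {shape}")
        if not (0 <= s0 < s1 <= shape[SLICE_AXIS]):
            raise ValueError(f"slice range {self.slice_range} outside grid {shape}")

    @classmethod
    def around_mask(cls, mask: LesionMask, pad: int = 3) -> "BoundingROI":
        """Rectangle/slab covering ``mask`` with a safety margin of ``pad`` voxels."""
        idx = np.argwhere(mask.data)
        if idx.size == 0:
            raise ValueError("cannot place ROI around an empty mask")
        lo = np.maximum(idx.min(axis=0) - pad, 0)
        hi = np.minimum(idx.max(axis=0) + 1 + pad, mask.shape)
        return cls(rect=(int(lo[0]), int(hi[0]), int(lo[1]), int(hi[1])),
                   slice_range=(int(idx[:, 2].min()), int(idx[:, 2].max()) + 1))


def dice(a: np.ndarray | LesionMask, b: np.ndarray | LesionMask) -> float:
    """Dice overlap coefficient between two binary masks."""
    a = a.data if isinstance(a, LesionMask) else np.asarray(a, bool)
    b = b.data if isinstance(b, LesionMask) else np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
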