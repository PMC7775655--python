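import numpy as np
import pytest

from pituradiomics import ImageVolume, LesionMask, PhantomSpec, generate_phantom
from pituradiomics.features.discretize import DiscretizedROI


def make_volume(data, spacing=(1.0, 1.0, 1.0), modality="T1CE"):
    return ImageVolume(np.asarray(data, dtype=float), spacing, modality)


def make_mask(data, spacing=(1.0, 1.0, 1.0)):
    return LesionMask(np.asarray(data, dtype=bool), spacing)


def levels_to_roi(levels, n_levels, spacing=(1.0, 1.0, 1.0)):
    """Wrap a raw level grid (0 = outside) as a DiscretizedROI."""
    levels = np.asarray(levels, dtype=np.int32)
    return DiscretizedROI(levels, levels > 0, n_levels,
                          np.arange(n_levels + 1, dtype=float), spacing)


def sphere_mask(radius_mm, spacing=(1.0, 1.0, 1.0), pad=3):
    """Digitized sphere centered in its own grid."""
    shape = tuple(int(2 * radius_mm / s) + 2 * pad + 1 for s in spacing)
    center = tuple((n - 1) * s / 2 for n, s in zip(shape, spacing))
    ax = [(np.arange(n) * s - c) for n, s, c in zip(shape, spacing, center)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij", sparse=True)
    return LesionMask(gx**2 + gy**2 + gz**2 <= radius_mm**2, spacing)


@pytest.fixture(scope="session")
def small_phantom():
    """One small isotropic phantom shared across tests."""
    spec = PhantomSpec(grid_shape=(40, 40, 40), voxel_spacing_mm=(1, 1, 1),
                       tumor_radii_mm=(12, 10, 10), rng_seed=42)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def tiny_level_fixtures():
    """Random small level grids (<= 8x8x3) for exhaustive oracle checks."""
    rng = np.random.default_rng(2024)
    grids = []
    for shape, ng in [((4, 4, 1), 3), ((6, 5, 2), 4), ((8, 8, 3), 5),
                      ((5, 8, 3), 4), ((8, 3, 2), 6), ((7, 7, 3), 2)]:
        lv = rng.integers(1, ng + 1, size=shape).astype(np.int32)
        mask = rng.uniform(size=shape) < 0.8
        lv[~mask] = 0
        if (lv > 0).sum() < 4:
            lv[0, 0, 0] = 1
        grids.append((lv, ng))
    return grids
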