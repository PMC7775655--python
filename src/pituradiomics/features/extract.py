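"""Assemble the full 214-entry feature vector for one case."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..volume import ImageVolume, LesionMask
from .discretize import discretize
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .gldm import GLDM_NAMES, gldm_features
from .glcm import GLCM_NAMES, glcm_features
from .glrlm import GLRLM_NAMES, glrlm_features
from .glszm import GLSZM_NAMES, glszm_features
from .ngtdm import NGTDM_NAMES, ngtdm_features
from .shape import SHAPE_NAMES, shape_features

_FAMILIES = [
    ("firstorder", FIRSTORDER_NAMES),
    ("shape", SHAPE_NAMES),
    ("glcm", GLCM_NAMES),
    ("glrlm", GLRLM_NAMES),
    ("glszm", GLSZM_NAMES),
    ("ngtdm", NGTDM_NAMES),
    ("gldm", GLDM_NAMES),
]

#: canonical names of all 214 features: ``{modality}_{family}_{feature}``
FEATURE_NAMES = [
    f"{mod}_{fam}_{name}"
    for mod in ("t1ce", "t2")
    for fam, names in _FAMILIES
    for name in names
]
assert len(FEATURE_NAMES) == 214


def extract_all(t1ce: ImageVolume, t2: ImageVolume, mask: LesionMask,
                n_bins: int = 32) -> dict:
    """Extract all 214 features (107 per modality) from one case.

    Both volumes must share the mask grid. Shape features are computed once
    from the mask and duplicated under each modality namespace, keeping the
    per-modality feature count at 107 as in the standard bank layout.
    """
    for vol, tag in ((t1ce, "T1CE"), (t2, "T2")):
        if vol.shape != mask.shape:
            raise ValueError(f"{tag} volume grid {vol.shape} does not match mask {mask.shape}")
    shape = shape_features(mask)
    out: dict[str, float] = {}
    for prefix, vol in (("t1ce", t1ce), ("t2", t2)):
        d = discretize(vol, mask, n_bins)
        family_values = {
            "firstorder": first_order_features(vol, mask, n_bins),
            "shape": shape,
            "glcm": glcm_features(d),
            "glrlm": glrlm_features(d),
            "glszm": glszm_features(d),
            "ngtdm": ngtdm_features(d),
            "gldm": gldm_features(d),
        }
        for fam, names in _FAMILIES:
            vals = family_values[fam]
            for name in names:
                key = f"{prefix}_{fam}_{name}"
                v = float(vals[name])
                if not np.isfinite(v):
                    raise ValueError(f"non-finite value for feature {key}: {v}")
                out[key] = v
    assert list(out) == FEATURE_NAMES
    return out


def features_to_frame(rows: dict[str, dict]) -> pd.DataFrame:
    """Stack per-case feature dicts into a (case × 214) table."""
    return pd.DataFrame.from_dict(rows, orient="index")[FEATURE_NAMES]
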