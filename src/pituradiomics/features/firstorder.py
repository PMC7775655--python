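"""First-order (histogram) intensity features, 18 per ROI.

Conventions: variance and moment-based statistics use the population
(n-denominator) form; skewness is the standardized third moment and
kurtosis the *excess* kurtosis (normal ⇒ 0); both are defined as 0 for a
constant ROI. Entropy and uniformity are computed on the equal-width
histogram with the same bin count used for texture discretization.
"""

from __future__ import annotations

import numpy as np

from ..volume import ImageVolume, LesionMask

FIRSTORDER_NAMES = [
    "energy", "total_energy", "entropy", "minimum", "percentile10",
    "percentile90", "maximum", "mean", "median", "interquartile_range",
    "range", "mean_absolute_deviation", "robust_mean_absolute_deviation",
    "root_mean_squared", "skewness", "kurtosis", "variance", "uniformity",
]


def first_order_features(vol: ImageVolume, mask: LesionMask, n_bins: int = 32) -> dict:
    x = vol.data[mask.data]
    if x.size < 2:
        raise ValueError("first-order features require a mask with >= 2 voxels")
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population
    lo, hi = float(x.min()), float(x.max())

    if hi > lo:
        counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
        p = counts[counts > 0] / n
        entropy = float(-(p * np.log2(p)).sum())
        uniformity = float((counts / n) @ (counts / n))
    else:
        entropy, uniformity = 0.0, 1.0

    if var > 0:
        z = (x - mean) / np.sqrt(var)
        skewness = float((z**3).mean())
        kurtosis = float((z**4).mean()) - 3.0
    else:
        skewness, kurtosis = 0.0, 0.0

    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    inner = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(inner - inner.mean()).mean()) if inner.size else 0.0

    return {
        "energy": float((x**2).sum()),
        "total_energy": float((x**2).sum() * np.prod(vol.spacing)),
        "entropy": entropy,
        "minimum": lo,
        "percentile10": float(p10),
        "percentile90": float(p90),
        "maximum": hi,
        "mean": mean,
        "median": float(np.median(x)),
        "interquartile_range": float(p75 - p25),
        "range": hi - lo,
        "mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "robust_mean_absolute_deviation": rmad,
        "root_mean_squared": float(np.sqrt((x**2).mean())),
        "skewness": skewness,
        "kurtosis": kurtosis,
        "variance": var,
        "uniformity": uniformity,
    }
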