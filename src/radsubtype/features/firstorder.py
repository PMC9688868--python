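"""First-order (histogram) intensity statistics over the VOI.

Conventions: population (not sample) variance; Pearson kurtosis (not
excess); skewness and kurtosis defined as 0 for a constant VOI so no
NaN ever propagates into clustering. Entropy and uniformity are
computed on the discretized gray-level histogram; everything else on
the continuous (normalized) intensities.
"""

from __future__ import annotations

import numpy as np

from radsubtype.maps import VOIMask
from radsubtype.prep import DiscretizedVolume

FIRSTORDER_FEATURE_NAMES = (
    "energy",
    "total_energy",
    "entropy",
    "minimum",
    "percentile_10",
    "percentile_90",
    "maximum",
    "mean",
    "median",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "root_mean_squared",
    "skewness",
    "kurtosis",
    "variance",
    "uniformity",
)

__all__ = ["firstorder_features", "FIRSTORDER_FEATURE_NAMES"]


def firstorder_features(volume: np.ndarray, mask: VOIMask,
                        discrete: DiscretizedVolume) -> dict[str, float]:
    """The 18 first-order features of one channel over the mask."""
    if mask.empty:
        raise ValueError("cannot compute first-order features of an empty mask")
    x = np.asarray(volume, dtype=float)[mask.mask]
    n = x.size
    voxel_vol = float(np.prod(mask.spacing_mm))

    mean = float(x.mean())
    var = float(x.var())  # population
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    if sd > 0:
        z = (x - mean) / sd
        skewness = float(np.mean(z ** 3))
        kurtosis = float(np.mean(z ** 4))
    else:
        skewness = 0.0
        kurtosis = 0.0

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    levels = discrete.levels[mask.mask]
    p = np.bincount(levels, minlength=discrete.n_bins + 1)[1:] / n
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((p ** 2).sum())

    energy = float((x ** 2).sum())
    return {
        "energy": energy,
        "total_energy": voxel_vol * energy,
        "entropy": entropy,
        "minimum": float(x.min()),
        "percentile_10": float(p10),
        "percentile_90": float(p90),
        "maximum": float(x.max()),
        "mean": mean,
        "median": float(p50),
        "interquartile_range": float(p75 - p25),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "robust_mean_absolute_deviation": rmad,
        "root_mean_squared": float(np.sqrt((x ** 2).mean())),
        "skewness": skewness,
        "kurtosis": kurtosis,
        "variance": var,
        "uniformity": uniformity,
    }
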