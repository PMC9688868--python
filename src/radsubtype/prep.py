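"""Image preparation: isotropic resampling, VOI-based intensity
normalization, and gray-level discretization.

Processing order per sample: kinetic maps are computed on the native
grid, then image + maps are resampled to 1 mm isotropic with cubic
B-splines (the mask with nearest neighbour so it stays binary), then
each channel is normalized within the resampled mask — values are
clipped to ``mu +/- 3*sigma`` of the VOI gray levels and affinely
remapped to a common output range — and finally discretized into
equal-width bins for texture analysis. Normalizing within the VOI
makes channels with wildly different native scales (signal intensity,
percent enhancement, dimensionless ratios) comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from radsubtype.maps import VOIMask

__all__ = [
    "NormalizationParams", "DiscretizedVolume",
    "resample_isotropic", "normalize_mu3sigma", "discretize",
]


@dataclass
class NormalizationParams:
    """Parameters of one mu +/- 3 sigma intensity remap."""

    mu: float
    sigma: float
    clip_lo: float
    clip_hi: float
    out_range: tuple[float, float]


@dataclass
class DiscretizedVolume:
    """Integer gray levels in ``1..n_bins`` inside the mask, 0 outside."""

    levels: np.ndarray
    n_bins: int
    bin_edges: np.ndarray


def resample_isotropic(volume: np.ndarray,
                       spacing_in: tuple[float, float, float],
                       interp: str = "bspline",
                       spacing_out: tuple[float, float, float] = (1.0, 1.0, 1.0),
                       ) -> np.ndarray:
    """Resample a volume to isotropic spacing (default 1 mm).

    ``interp`` is ``"bspline"`` (cubic, for intensities) or
    ``"nearest"`` (for masks; output values stay in the input value
    set). Input already on the target spacing is returned unchanged —
    grid points are interpolation fixed points.
    """
    spacing_in = tuple(float(s) for s in spacing_in)
    spacing_out = tuple(float(s) for s in spacing_out)
    if any(s <= 0 for s in spacing_in):
        raise ValueError(f"non-positive input spacing {spacing_in}")
    volume = np.asarray(volume)
    if not np.all(np.isfinite(volume)):
        raise ValueError("cannot resample non-finite volume")
    if spacing_in == spacing_out:
        return volume.copy()

    was_bool = volume.dtype == bool
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(volume.astype(np.float64).T))
    img.SetSpacing(spacing_in)  # sitk spacing order matches axis 0,1,2 here
    # cover the input grid's physical extent without extrapolating
    new_size = [
        max(1, int(np.floor((volume.shape[i] - 1) * spacing_in[i]
                            / spacing_out[i])) + 1)
        for i in range(3)
    ]
    resampler = sitk.ResampleImageFilter()
    resampler.SetOutputSpacing(spacing_out)
    resampler.SetSize(new_size)
    resampler.SetOutputOrigin(img.GetOrigin())
    resampler.SetOutputDirection(img.GetDirection())
    if interp == "bspline":
        resampler.SetInterpolator(sitk.sitkBSpline)
    elif interp == "nearest":
        resampler.SetInterpolator(sitk.sitkNearestNeighbor)
    else:
        raise ValueError(f"unknown interpolator {interp!r}")
    out = sitk.GetArrayFromImage(resampler.Execute(img)).T
    if was_bool:
        out = out > 0.5
    return out


def normalize_mu3sigma(volume: np.ndarray, mask: VOIMask,
                       out_range: tuple[float, float] = (0.0, 100.0),
                       ) -> tuple[np.ndarray, NormalizationParams]:
    """Clip to ``mu +/- 3*sigma`` of the VOI and remap affinely.

    mu and sigma are the mean and (population) standard deviation of
    gray levels inside the segmentation mask. Values are clipped to
    ``[mu - 3s, mu + 3s]`` and mapped so those endpoints land on
    ``out_range``. The whole volume is transformed with the same
    affine map so masked and unmasked voxels stay consistent. A
    constant VOI (sigma = 0) maps every voxel to the range midpoint.
    """
    if mask.empty:
        raise ValueError("cannot normalize with an empty mask")
    volume = np.asarray(volume, dtype=float)
    inside = volume[mask.mask]
    mu = float(inside.mean())
    sigma = float(inside.std())
    lo, hi = float(out_range[0]), float(out_range[1])
    clip_lo, clip_hi = mu - 3.0 * sigma, mu + 3.0 * sigma
    params = NormalizationParams(mu, sigma, clip_lo, clip_hi, (lo, hi))
    if sigma == 0.0:
        return np.full_like(volume, 0.5 * (lo + hi)), params
    clipped = np.clip(volume, clip_lo, clip_hi)
    out = lo + (clipped - clip_lo) * (hi - lo) / (clip_hi - clip_lo)
    return out, params


def discretize(volume: np.ndarray, mask: VOIMask, n_bins: int = 32,
               ) -> DiscretizedVolume:
    """Equal-width binning of mask voxels into levels ``1..n_bins``.

    Bins cover ``[min, max]`` of the mask voxels; the maximum maps to
    level ``n_bins``. A constant volume gets level 1 everywhere inside
    the mask. Voxels outside the mask hold level 0.
    """
    if mask.empty:
        raise ValueError("cannot discretize with an empty mask")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    volume = np.asarray(volume, dtype=float)
    inside = volume[mask.mask]
    vmin, vmax = float(inside.min()), float(inside.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if vmax == vmin:
        edges = np.linspace(vmin, vmin + 1.0, n_bins + 1)
        levels[mask.mask] = 1
        return DiscretizedVolume(levels, n_bins, edges)
    edges = np.linspace(vmin, vmax, n_bins + 1)
    width = (vmax - vmin) / n_bins
    lev = np.floor((inside - vmin) / width).astype(np.int32) + 1
    np.clip(lev, 1, n_bins, out=lev)
    levels[mask.mask] = lev
    return DiscretizedVolume(levels, n_bins, edges)
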