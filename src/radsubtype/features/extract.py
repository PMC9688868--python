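"""Per-sample feature-vector assembly and cohort feature tables.

One sample yields exactly 174 features:

* ``pre`` channel (pre-contrast image): 14 shape + 18 first-order +
  22 GLCM = 54;
* ``peE``, ``serM``, ``serL`` channels (early PE, middle SER, late
  SER maps): 18 first-order + 22 GLCM = 40 each.

Shape features describe the mask alone, so they appear only once.
Pipeline per sample: maps on the native grid -> B-spline resample of
image + maps and nearest-neighbour resample of the mask to 1 mm
isotropic -> per-channel mu+/-3sigma normalization within the mask ->
32-level discretization -> feature kernels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from radsubtype.maps import DCESeries, VOIMask, compute_pe_early, compute_ser
from radsubtype.prep import resample_isotropic, normalize_mu3sigma, discretize
from radsubtype.features.shape import shape_features, SHAPE_FEATURE_NAMES
from radsubtype.features.firstorder import (
    firstorder_features, FIRSTORDER_FEATURE_NAMES)
from radsubtype.features.glcm import (
    glcm_compute, glcm_features, GLCM_FEATURE_NAMES)

CHANNELS = ("pre", "peE", "serM", "serL")

__all__ = ["FeatureConfig", "CHANNELS", "feature_names",
           "extract_feature_vector", "build_feature_table"]


@dataclass
class FeatureConfig:
    """Knobs of the extraction pipeline."""

    n_bins: int = 32
    out_range: tuple[float, float] = (0.0, 100.0)
    eps: float = 1e-6
    ser_cap: float = 10.0
    resample: bool = True

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def feature_names() -> list[str]:
    """The 174 feature names in canonical order."""
    names = [f"pre__shape__{n}" for n in SHAPE_FEATURE_NAMES]
    for channel in CHANNELS:
        names += [f"{channel}__firstorder__{n}"
                  for n in FIRSTORDER_FEATURE_NAMES]
        names += [f"{channel}__glcm__{n}" for n in GLCM_FEATURE_NAMES]
    return names


def _crop_to_mask(arrays: dict[str, np.ndarray], mask: np.ndarray,
                  margin: int = 1):
    """Crop all channels to the mask bounding box (plus margin).

    First-order and GLCM kernels only look at intra-mask voxels, so
    cropping changes nothing but the run time.
    """
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return {k: v[sl] for k, v in arrays.items()}, mask[sl]


def extract_feature_vector(series: DCESeries, mask: VOIMask,
                           config: FeatureConfig | None = None,
                           ) -> dict[str, float]:
    """Extract the 174-feature vector for one sample.

    Requires all four timepoints. Raises on an empty mask or grid
    mismatch; the error message names the failing channel.
    """
    config = config or FeatureConfig()
    if mask.empty:
        raise ValueError("empty tumor mask")
    if mask.mask.shape != series.shape:
        raise ValueError("mask grid does not match series grid")

    pe = compute_pe_early(series, eps=config.eps)
    ser_m = compute_ser(series, "middle", eps=config.eps,
                        ser_cap=config.ser_cap)
    ser_l = compute_ser(series, "late", eps=config.eps,
                        ser_cap=config.ser_cap)
    channels = {
        "pre": np.asarray(series["pre"], dtype=float),
        "peE": pe.values,
        "serM": ser_m.values,
        "serL": ser_l.values,
    }

    if config.resample:
        channels = {
            name: resample_isotropic(vol, series.spacing_mm, "bspline")
            for name, vol in channels.items()
        }
        mask_arr = resample_isotropic(mask.mask, mask.spacing_mm, "nearest")
        spacing = (1.0, 1.0, 1.0)
    else:
        mask_arr = mask.mask
        spacing = series.spacing_mm
    if not mask_arr.any():
        raise ValueError("mask became empty after resampling")

    channels, mask_arr = _crop_to_mask(channels, mask_arr)
    voi = VOIMask(mask_arr, spacing)

    out: dict[str, float] = {}
    for name, value in shape_features(voi).items():
        out[f"pre__shape__{name}"] = value
    for channel in CHANNELS:
        try:
            norm, _ = normalize_mu3sigma(channels[channel], voi,
                                         config.out_range)
            disc = discretize(norm, voi, config.n_bins)
            for name, value in firstorder_features(norm, voi, disc).items():
                out[f"{channel}__firstorder__{name}"] = value
            g = glcm_compute(disc, voi)
            for name, value in glcm_features(g).items():
                out[f"{channel}__glcm__{name}"] = value
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed on channel {channel!r}: {exc}"
            ) from exc
    assert len(out) == 174
    return out


def build_feature_table(samples, config: FeatureConfig | None = None,
                        ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Extract features for an iterable of ``(sample_id, series, mask)``.

    Returns a ``(table, errors)`` pair: a samples x 174 DataFrame in
    canonical column order, and a dict of per-sample error messages
    for samples that failed (they are excluded from the table, never
    silently dropped).
    """
    config = config or FeatureConfig()
    rows: dict[str, dict[str, float]] = {}
    errors: dict[str, str] = {}
    for sample_id, series, mask in samples:
        try:
            rows[str(sample_id)] = extract_feature_vector(series, mask, config)
        except Exception as exc:
            errors[str(sample_id)] = str(exc)
    table = pd.DataFrame.from_dict(rows, orient="index")
    if len(table):
        table = table[feature_names()]
    table.attrs["config_hash"] = config.hash()
    return table, errors
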