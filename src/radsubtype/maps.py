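"""Voxel-wise enhancement maps from a registered DCE-MRI series.

Two derived maps summarise contrast kinetics per voxel:

* percentage enhancement at the early post-contrast phase,
  ``PE = 100 * (I_early - I_pre) / I_pre`` — relative signal uptake;
* signal enhancement ratio at the middle or late phase,
  ``SER = (I_early - I_pre) / (I_phase - I_pre)`` — values above 1
  indicate washout after the early peak, values near 1 persistence.

The series is assumed to be spatially registered already: all
timepoint volumes share one grid, and only shape/spacing equality is
validated here. Division-by-(near-)zero voxels are eps-guarded: they
are set to 0 and excluded from the map's validity mask so that no
NaN/Inf ever reaches the feature extractors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

TIMEPOINTS = ("pre", "early", "middle", "late")

__all__ = [
    "DCESeries", "VOIMask", "EnhancementMap",
    "compute_pe_early", "compute_ser", "subtraction_volume",
    "threshold_segment",
]


class GridError(ValueError):
    """Volumes of one series do not share a common grid."""


@dataclass
class DCESeries:
    """Aligned 3D volumes at labelled timepoints of one DCE acquisition.

    Parameters
    ----------
    volumes
        Mapping from timepoint label (subset of ``pre, early, middle,
        late``; ``pre`` and ``early`` mandatory) to a 3D float array of
        signal intensities in arbitrary units.
    spacing_mm
        Per-axis voxel size in millimetres.
    """

    volumes: dict[str, np.ndarray]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        for required in ("pre", "early"):
            if required not in self.volumes:
                raise ValueError(f"series must contain a {required!r} volume")
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1:
            raise GridError(f"timepoint volumes differ in shape: {shapes}")
        for label, vol in self.volumes.items():
            if vol.ndim != 3:
                raise GridError(f"volume {label!r} is not 3D")
            if not np.all(np.isfinite(vol)):
                raise ValueError(f"volume {label!r} contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes["pre"].shape

    def __getitem__(self, label: str) -> np.ndarray:
        return self.volumes[label]


@dataclass
class VOIMask:
    """Binary 3D tumor segmentation (volume of interest).

    ``empty`` is True when segmentation found no voxel; downstream
    feature extraction refuses empty masks, but carrying the flag lets
    batch runs report the failure instead of crashing.
    """

    mask: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise GridError("mask is not 3D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def empty(self) -> bool:
        return self.voxel_count == 0

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing_mm))


@dataclass
class EnhancementMap:
    """A per-voxel derived kinetic map on the series grid.

    ``valid_mask`` marks voxels where the defining ratio was
    well-conditioned; degenerate voxels hold 0 and are excluded.
    """

    kind: str  # PE_early | SER_middle | SER_late
    values: np.ndarray
    valid_mask: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("enhancement map contains non-finite values")


def compute_pe_early(series: DCESeries, eps: float = 1e-6) -> EnhancementMap:
    """Early percentage-enhancement map: ``100 * (early - pre) / pre``.

    Voxels whose pre-contrast intensity is at or below ``eps`` are set
    to 0 and flagged invalid.
    """
    pre = np.asarray(series["pre"], dtype=float)
    early = np.asarray(series["early"], dtype=float)
    valid = pre > eps
    values = np.zeros_like(pre)
    np.divide(100.0 * (early - pre), pre, out=values, where=valid)
    values[~valid] = 0.0
    return EnhancementMap("PE_early", values, valid, series.spacing_mm)


def compute_ser(series: DCESeries, phase: str = "late", eps: float = 1e-6,
                ser_cap: float = 10.0) -> EnhancementMap:
    """Signal-enhancement-ratio map ``(early - pre) / (phase - pre)``.

    Parameters
    ----------
    phase
        ``"middle"`` or ``"late"`` — the denominator timepoint.
    ser_cap
        Values are clipped to ``[0, ser_cap]``; the unclipped ratio has
        heavy tails near ``I_phase ~ I_pre`` that would otherwise
        dominate histogram discretization.

    Voxels with ``|I_phase - I_pre| <= eps`` or ``I_pre <= eps`` are
    set to 0 and flagged invalid.
    """
    if phase not in ("middle", "late"):
        raise ValueError(f"phase must be 'middle' or 'late', got {phase!r}")
    if phase not in series.volumes:
        raise ValueError(f"series has no {phase!r} volume")
    pre = np.asarray(series["pre"], dtype=float)
    early = np.asarray(series["early"], dtype=float)
    phase_vol = np.asarray(series[phase], dtype=float)
    denom = phase_vol - pre
    valid = (np.abs(denom) > eps) & (pre > eps)
    values = np.zeros_like(pre)
    np.divide(early - pre, denom, out=values, where=valid)
    values[~valid] = 0.0
    np.clip(values, 0.0, ser_cap, out=values)
    kind = "SER_middle" if phase == "middle" else "SER_late"
    return EnhancementMap(kind, values, valid, series.spacing_mm)


def subtraction_volume(series: DCESeries) -> np.ndarray:
    """First-enhanced subtraction image, ``I_early - I_pre``."""
    return np.asarray(series["early"], dtype=float) - np.asarray(
        series["pre"], dtype=float)


# 26-connectivity in 3D
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def threshold_segment(subtraction: np.ndarray, threshold: float,
                      min_component_voxels: int = 1,
                      spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
                      ) -> VOIMask:
    """Threshold segmentation of the subtraction image.

    Keeps the largest 26-connected component of ``subtraction >
    threshold`` provided it has at least ``min_component_voxels``
    voxels; otherwise returns an empty mask (with a warning).
    """
    subtraction = np.asarray(subtraction, dtype=float)
    if not np.all(np.isfinite(subtraction)):
        raise ValueError("subtraction volume contains non-finite values")
    binary = subtraction > threshold
    labels, n = ndimage.label(binary, structure=_STRUCT_26)
    if n == 0:
        warnings.warn("threshold segmentation produced an empty mask")
        return VOIMask(np.zeros_like(binary), spacing_mm)
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_component_voxels:
        warnings.warn(
            f"largest component ({sizes[best - 1]} voxels) below "
            f"min_component_voxels={min_component_voxels}; empty mask")
        return VOIMask(np.zeros_like(binary), spacing_mm)
    return VOIMask(labels == best, spacing_mm)
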