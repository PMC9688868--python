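"""Reading and writing cohorts: NIfTI volumes plus CSV/TSV tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from radsubtype.maps import DCESeries, VOIMask, TIMEPOINTS
from radsubtype.synthetic import SyntheticCohort

__all__ = ["save_volume", "load_volume", "write_cohort", "read_series"]


def save_volume(path, volume: np.ndarray,
                spacing_mm=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), spacing


def read_series(sample_dir: Path) -> tuple[DCESeries, VOIMask]:
    """Load one sample directory written by :func:`write_cohort`."""
    sample_dir = Path(sample_dir)
    volumes = {}
    spacing = (1.0, 1.0, 1.0)
    for label in TIMEPOINTS:
        path = sample_dir / f"{label}.nii.gz"
        if path.exists():
            volumes[label], spacing = load_volume(path)
    mask_arr, mask_spacing = load_volume(sample_dir / "mask.nii.gz")
    return (DCESeries(volumes, spacing),
            VOIMask(mask_arr > 0.5, mask_spacing))


def write_cohort(cohort: SyntheticCohort, out_dir) -> pd.DataFrame:
    """Write a cohort: per-sample NIfTI volumes + mask, a manifest
    CSV, expression TSV (genes x samples) and survival CSV. Returns
    the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sample_id in enumerate(cohort.sample_ids):
        row = {"sample_id": sample_id,
               "phenotype": str(cohort.truth_labels[i])}
        if cohort.series_list:
            sdir = out_dir / sample_id
            sdir.mkdir(exist_ok=True)
            series = cohort.series_list[i]
            for label, vol in series.volumes.items():
                save_volume(sdir / f"{label}.nii.gz", vol, series.spacing_mm)
            save_volume(sdir / "mask.nii.gz",
                        cohort.mask_list[i].mask.astype(np.uint8),
                        cohort.mask_list[i].spacing_mm)
            row["path"] = str(sdir)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    cohort.expression.to_csv(out_dir / "expression.tsv", sep="\t")
    cohort.survival.to_csv(out_dir / "survival.csv", index=False)
    return manifest
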