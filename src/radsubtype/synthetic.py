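"""Synthetic DCE-MRI cohorts with three planted imaging phenotypes.

The generator emulates the statistical structure the subtyping
pipeline assumes rather than scanner physics. Each sample is an
ellipsoidal tumor with a perturbed boundary placed in a smooth
baseline tissue volume; its four timepoints (pre, early, middle,
late) are built from per-voxel enhancement fields chosen so the
defining map equations recover the phenotype's targets exactly before
noise:

* early percentage enhancement (PE) inside the tumor is
  ``pe_early_mean * (1 + a * G)`` with G a unit-variance Gaussian
  random field of phenotype-specific correlation length (the texture
  carrier) standardized within the tumor, so the pre-noise tumor mean
  equals the target;
* the late volume is placed so the voxelwise late signal-enhancement
  ratio (SER) field has tumor mean ``ser_late_mean`` (> 1 encodes
  washout, = 1 persistence); the middle SER interpolates halfway
  between 1 and the late target.

The three default phenotypes follow the reported imaging subtypes:
S1 small with general enhancement, S2 large with rapid enhancement
and washout, S3 large with general enhancement; S1/S2/S3 carry
increasing texture correlation lengths so GLCM features — not only
shape and first-order statistics — separate them. Matched gene
expression is negative-binomial with a subset of subtype-informative
genes, and survival is exponential with phenotype hazards ordered
S2 > S3 > S1 (worst to best prognosis).

Noise is additive Gaussian on magnitude images (not Rician): at the
simulated signal-to-noise level the difference is negligible and the
additive model keeps the map calibration exact in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.ndimage import distance_transform_edt, gaussian_filter

from radsubtype.maps import DCESeries, VOIMask

__all__ = [
    "PhenotypeSpec", "CohortConfig", "SyntheticCohort",
    "default_phenotypes", "generate_tumor_mask", "generate_dce_series",
    "generate_expression", "generate_survival", "generate_cohort",
]


class SizingError(ValueError):
    """Requested tumor volume cannot fit in the configured grid."""


@dataclass(frozen=True)
class PhenotypeSpec:
    """One planted imaging phenotype.

    Parameters
    ----------
    target_volume_mm3, volume_sd_mm3
        Mean and SD of the tumor volume draw.
    pe_early_mean
        Expected tumor-mean early percentage enhancement (percent).
    ser_late_mean
        Expected tumor-mean late SER (dimensionless; > 1 washout).
    texture_corr_len_mm
        Correlation length of the within-tumor heterogeneity field.
    hazard_rate
        Exponential event rate per unit follow-up time.
    """

    name: str
    target_volume_mm3: float
    volume_sd_mm3: float
    pe_early_mean: float
    ser_late_mean: float
    texture_corr_len_mm: float
    hazard_rate: float
    rim_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.target_volume_mm3 <= 0:
            raise ValueError("target_volume_mm3 must be positive")
        if self.pe_early_mean <= 0 or self.ser_late_mean <= 0:
            raise ValueError("enhancement targets must be positive")
        if self.hazard_rate <= 0:
            raise ValueError("hazard_rate must be positive")


def default_phenotypes() -> dict[str, PhenotypeSpec]:
    """The three default phenotypes.

    Volumes are set to the subtype mean voxel volumes reported for the
    three imaging subtypes (1458.66 / 8564.07 / 8258.59 mm^3); S2 gets
    a high early-PE, high late-SER (rapid enhancement + washout)
    profile, S1 and S3 a general enhancement profile; hazards are
    ordered S2 > S3 > S1 so median survival orders S1 > S3 > S2.
    """
    return {
        "S1": PhenotypeSpec("S1", 1458.66, 300.0, 120.0, 1.00, 1.2, 0.05,
                            rim_weight=0.0),
        "S2": PhenotypeSpec("S2", 8564.07, 1500.0, 220.0, 1.60, 6.0, 0.20,
                            rim_weight=0.7),
        "S3": PhenotypeSpec("S3", 8258.59, 2000.0, 130.0, 1.05, 3.0, 0.10,
                            rim_weight=-0.7),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator settings (defaults are the study
    conditions used throughout the test-suite and examples)."""

    n_samples: int = 60
    phenotype_mix: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    baseline_mean: float = 100.0
    baseline_sd: float = 5.0
    noise_sd: float = 2.0
    heterogeneity: float = 0.3      # relative amplitude of the texture field
    background_pe: float = 5.0      # weak background enhancement, percent
    n_genes: int = 2000
    n_informative_genes: int = 100
    lfc_scale: float = 1.0          # log2-fold-change magnitude
    nb_dispersion: float = 0.1
    censor_rate: float = 0.2
    seed: int = 0
    # the gene "biology" (which genes are informative, their
    # per-subtype shifts, baseline means) is fixed by its own seed so
    # that independent cohorts share one expression model, as real
    # discovery/validation cohorts do
    gene_model_seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")
        if self.n_informative_genes > self.n_genes:
            raise ValueError("n_informative_genes must be <= n_genes")
        if abs(sum(self.phenotype_mix) - 1.0) > 1e-9:
            raise ValueError("phenotype_mix must sum to 1")
        if any(p < 0 for p in self.phenotype_mix):
            raise ValueError("phenotype_mix must be nonnegative")


@dataclass
class SyntheticCohort:
    """Everything the downstream pipeline consumes, plus ground truth."""

    sample_ids: list[str]
    series_list: list[DCESeries]
    mask_list: list[VOIMask]
    truth_labels: np.ndarray                # phenotype name per sample
    expression: pd.DataFrame                # genes x samples counts
    survival: pd.DataFrame                  # sample_id, time, event
    informative_genes: list[str]
    config: CohortConfig


def _smooth_field(shape, sigma_vox, rng) -> np.ndarray:
    """Smoothed white noise; approximately Gaussian with the given
    correlation scale, not normalized."""
    field = rng.standard_normal(shape)
    return gaussian_filter(field, sigma=sigma_vox, mode="nearest")


def _standardize_in(field: np.ndarray, mask: np.ndarray) -> np.ndarray:
    inside = field[mask]
    sd = inside.std()
    if sd == 0:
        return np.zeros_like(field)
    return (field - inside.mean()) / sd


def generate_tumor_mask(spec: PhenotypeSpec, config: CohortConfig,
                        rng: np.random.Generator) -> VOIMask:
    """Random perturbed ellipsoid with the phenotype's target volume.

    The volume is drawn from ``N(target, sd)``; axis ratios are
    uniform in [0.6, 1] with the shortest axis along z (the thin grid
    dimension) and a random in-plane rotation; the boundary is
    perturbed by a smooth random field. Raises :class:`SizingError`
    when the ellipsoid cannot fit the grid with a 2-voxel margin.
    """
    nx, ny, nz = config.grid_shape
    sp = np.asarray(config.spacing_mm)
    target = float(rng.normal(spec.target_volume_mm3, spec.volume_sd_mm3))
    target = max(target, 8.0 * float(np.prod(sp)))  # at least a few voxels
    r2, r3 = rng.uniform(0.6, 1.0, size=2)
    base_r = (3.0 * target / (4.0 * math.pi)) ** (1.0 / 3.0)
    a = base_r / (r2 * r3) ** (1.0 / 3.0)
    b, c = r2 * a, r3 * a
    # shortest semi-axis along z; in-plane axes in random orientation
    ax_xy = sorted([a, b, c], reverse=True)
    a_x, a_y, a_z = ax_xy[0], ax_xy[1], min(a, b, c)
    half_extent_mm = np.array([nx, ny, nz]) * sp / 2.0
    z_limit = half_extent_mm[2] - 3.0 * sp[2]
    if a_z > z_limit:
        # flatten at constant volume: big tumors become oblate rather
        # than overflowing the thin z slab
        scale = math.sqrt(a_z / z_limit)
        a_x, a_y, a_z = a_x * scale, a_y * scale, z_limit
    if (a_x > half_extent_mm[0] - 2 * sp[0]
            or a_y > half_extent_mm[1] - 2 * sp[1]):
        raise SizingError(
            f"tumor of volume {target:.0f} mm^3 does not fit grid "
            f"{config.grid_shape} at spacing {config.spacing_mm}")

    theta = rng.uniform(0, math.pi)
    jitter = rng.uniform(-2.0, 2.0, size=3)
    center = (np.array([nx, ny, nz]) - 1) / 2.0 * sp + jitter

    idx = np.indices((nx, ny, nz)).astype(float)
    x = idx[0] * sp[0] - center[0]
    y = idx[1] * sp[1] - center[1]
    z = idx[2] * sp[2] - center[2]
    u = x * math.cos(theta) + y * math.sin(theta)
    v = -x * math.sin(theta) + y * math.cos(theta)
    quad = (u / a_x) ** 2 + (v / a_y) ** 2 + (z / a_z) ** 2

    perturb = _smooth_field((nx, ny, nz), 3.0, rng)
    perturb = perturb / max(perturb.std(), 1e-12)
    mask = quad <= 1.0 + 0.15 * perturb
    if not mask.any():
        mask = quad <= 1.0
    # boundary perturbation may split off fragments; keep the main body
    labeled, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    if n_comp > 1:
        sizes = np.bincount(labeled.ravel())[1:]
        mask = labeled == (int(np.argmax(sizes)) + 1)
    return VOIMask(mask, config.spacing_mm)


def generate_dce_series(mask: VOIMask, spec: PhenotypeSpec,
                        config: CohortConfig,
                        rng: np.random.Generator) -> DCESeries:
    """Four-timepoint series whose map statistics match the phenotype.

    Pre-noise, the tumor-mean early PE equals ``pe_early_mean`` and
    the tumor-mean late SER equals ``ser_late_mean`` exactly (up to
    the clipping that keeps both fields positive); background voxels
    enhance weakly (PE < 10). Gaussian noise of SD ``noise_sd`` is
    added to every timepoint.
    """
    m = mask.mask
    sp = np.asarray(config.spacing_mm)
    shape = m.shape

    baseline = config.baseline_mean + _standardize_in(
        _smooth_field(shape, 8.0, rng),
        np.ones(shape, bool)) * config.baseline_sd
    np.clip(baseline, 0.1 * config.baseline_mean, None, out=baseline)

    sigma_vox = spec.texture_corr_len_mm / sp.mean()
    texture = _standardize_in(_smooth_field(shape, sigma_vox, rng), m)
    # deterministic radial profile: rim_weight > 0 concentrates
    # enhancement at the tumor boundary (rim enhancement), < 0 at the
    # core; 0 is spatially homogeneous in expectation
    depth = distance_transform_edt(m, sampling=sp)
    radial = -_standardize_in(depth, m)  # high at the boundary

    pattern = config.heterogeneity * texture + spec.rim_weight * radial
    pe = np.full(shape, config.background_pe)
    pe[m] = spec.pe_early_mean * (1.0 + pattern[m])
    np.clip(pe, 1.0, None, out=pe)

    ser_field = np.ones(shape)
    ser_texture = _standardize_in(_smooth_field(shape, sigma_vox, rng), m)
    ser_field[m] = spec.ser_late_mean * (
        1.0 + 0.1 * ser_texture[m] + 0.3 * spec.rim_weight * radial[m])
    np.clip(ser_field, 0.3, None, out=ser_field)
    ser_mid = 0.5 * (1.0 + ser_field)

    pre = baseline
    uptake = pre * pe / 100.0
    early = pre + uptake
    middle = pre + uptake / ser_mid
    late = pre + uptake / ser_field

    volumes = {}
    for label, vol in (("pre", pre), ("early", early),
                       ("middle", middle), ("late", late)):
        noisy = vol + config.noise_sd * rng.standard_normal(shape)
        volumes[label] = np.clip(noisy, 0.0, None)
    return DCESeries(volumes, config.spacing_mm)


def _allocate_labels(config: CohortConfig, names: list[str],
                     rng: np.random.Generator) -> np.ndarray:
    """Deterministic counts from the mix proportions (largest-remainder
    rounding), then a random permutation of the sample order."""
    n = config.n_samples
    raw = np.asarray(config.phenotype_mix) * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(names, counts)
    return labels[rng.permutation(n)]


def generate_expression(truth_labels: np.ndarray, config: CohortConfig,
                        rng: np.random.Generator,
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Negative-binomial counts with subtype-informative genes.

    Each gene has a baseline mean drawn log-normally; exactly
    ``n_informative_genes`` randomly chosen genes get per-subtype
    multiplicative shifts of magnitude ``2**lfc_scale`` (one subtype
    up, one down, one unchanged, in random assignment), all other
    genes keep one mean across subtypes. The gene model itself —
    baseline means, informative set and shift pattern — is drawn from
    ``config.gene_model_seed``, not from ``rng``, so cohorts generated
    with different sampling seeds share the same expression biology
    and a classifier trained on one transfers to another. Returns the
    genes x samples count matrix and the informative gene ids.
    """
    n_samples = len(truth_labels)
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    model_rng = np.random.default_rng(config.gene_model_seed)
    base_mean = model_rng.lognormal(mean=math.log(50.0), sigma=1.0,
                                    size=config.n_genes)

    subtypes = sorted(set(truth_labels))
    mu = np.tile(base_mean[:, None], (1, n_samples))
    informative = model_rng.choice(config.n_genes,
                                   config.n_informative_genes,
                                   replace=False)
    informative.sort()
    offsets = np.linspace(-1.0, 1.0, len(subtypes))  # one down, one up
    for gi in informative:
        per_subtype = model_rng.permutation(offsets) * config.lfc_scale
        for s_off, subtype in zip(per_subtype, subtypes):
            cols = np.asarray(truth_labels) == subtype
            mu[gi, cols] *= 2.0 ** s_off

    if config.nb_dispersion > 0:
        size = 1.0 / config.nb_dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(mu)
    expr = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    return expr, [gene_ids[i] for i in informative]


def generate_survival(truth_labels: np.ndarray,
                      specs: dict[str, PhenotypeSpec],
                      config: CohortConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Exponential event times with phenotype hazards and independent
    censoring: with probability ``censor_rate`` a sample is censored
    uniformly over its own follow-up."""
    for label in set(truth_labels):
        if label not in specs:
            raise ValueError(f"no phenotype spec for label {label!r}")
    n = len(truth_labels)
    hazards = np.array([specs[l].hazard_rate for l in truth_labels])
    t_event = rng.exponential(1.0 / hazards)
    censored = rng.uniform(size=n) < config.censor_rate
    time = np.where(censored, rng.uniform(size=n) * t_event, t_event)
    time = np.maximum(time, 1e-6)
    return pd.DataFrame({
        "sample_id": [f"s{i:03d}" for i in range(n)],
        "time": time,
        "event": (~censored).astype(int),
    })


def generate_cohort(config: CohortConfig | None = None,
                    specs: dict[str, PhenotypeSpec] | None = None,
                    seed: int | None = None,
                    with_images: bool = True) -> SyntheticCohort:
    """Generate a full cohort: images + masks, expression, survival.

    Identical ``config`` + ``seed`` give a bit-identical cohort.
    ``with_images=False`` skips the imaging volumes (for expression /
    survival studies) and leaves the series and mask lists empty.
    """
    config = config or CohortConfig()
    specs = specs or default_phenotypes()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    names = sorted(specs)
    labels = _allocate_labels(config, names, rng)
    sample_ids = [f"s{i:03d}" for i in range(config.n_samples)]

    series_list: list[DCESeries] = []
    mask_list: list[VOIMask] = []
    if with_images:
        for label in labels:
            mask = generate_tumor_mask(specs[label], config, rng)
            series_list.append(
                generate_dce_series(mask, specs[label], config, rng))
            mask_list.append(mask)

    expression, informative = generate_expression(labels, config, rng)
    survival = generate_survival(labels, specs, config, rng)
    return SyntheticCohort(sample_ids, series_list, mask_list,
                           np.asarray(labels), expression, survival,
                           informative, config)
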