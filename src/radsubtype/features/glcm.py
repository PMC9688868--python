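"""Gray-level co-occurrence matrices and the 22 texture features.

Co-occurrences are counted between intra-mask voxel pairs at the 13
unique 3D offsets of Chebyshev distance 1 (each offset and its
negation collapse to one symmetric matrix: every ordered pair is
accumulated in both (i, j) and (j, i)). Each feature is evaluated per
offset on the normalized matrix and averaged over offsets that
contained at least one pair.

Notation below: p(i, j) the co-occurrence probability for levels
i, j in 1..Ng; px, py its marginals; mu_x, sigma_x etc. their moments;
p_{x+y}(k) and p_{x-y}(k) the diagonal/cross-diagonal sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from radsubtype.maps import VOIMask
from radsubtype.prep import DiscretizedVolume

# the 13 lexicographically-positive neighbours at Chebyshev distance 1
OFFSETS_3D = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

GLCM_FEATURE_NAMES = (
    "autocorrelation",
    "joint_average",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "joint_energy",
    "joint_entropy",
    "imc1",
    "imc2",
    "idm",
    "idmn",
    "id",
    "idn",
    "inverse_variance",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
)

__all__ = ["GLCMatrix", "glcm_compute", "glcm_features",
           "GLCM_FEATURE_NAMES", "OFFSETS_3D"]


@dataclass
class GLCMatrix:
    """Symmetric co-occurrence counts and probabilities per offset."""

    counts: np.ndarray        # (n_offsets, Ng, Ng)
    offsets: tuple[tuple[int, int, int], ...]
    n_bins: int

    @property
    def probabilities(self) -> np.ndarray:
        totals = self.counts.sum(axis=(1, 2), keepdims=True)
        with np.errstate(invalid="ignore"):
            p = np.where(totals > 0, self.counts / np.maximum(totals, 1), 0.0)
        return p


def glcm_compute(discrete: DiscretizedVolume, mask: VOIMask) -> GLCMatrix:
    """Count intra-mask level co-occurrences at the 13 offsets."""
    if mask.voxel_count < 2:
        raise ValueError("GLCM needs a mask with at least 2 voxels")
    levels = discrete.levels
    m = mask.mask
    ng = discrete.n_bins
    counts = np.zeros((len(OFFSETS_3D), ng, ng), dtype=np.int64)

    for oi, (dx, dy, dz) in enumerate(OFFSETS_3D):
        src = _shift_slices((dx, dy, dz), levels.shape)
        dst = _shift_slices((-dx, -dy, -dz), levels.shape)
        both = m[src] & m[dst]
        a = levels[src][both] - 1
        b = levels[dst][both] - 1
        flat = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng)
        counts[oi] = flat + flat.T  # symmetric accumulation
    return GLCMatrix(counts, OFFSETS_3D, ng)


def _shift_slices(offset, shape):
    out = []
    for d, size in zip(offset, shape):
        if d >= 0:
            out.append(slice(d, size))
        else:
            out.append(slice(0, size + d))
    return tuple(out)


def _features_one(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    def xlog2(v):
        v = np.asarray(v, dtype=float)
        out = np.zeros_like(v)
        nz = v > 0
        out[nz] = v[nz] * np.log2(v[nz])
        return out

    # diagonal distributions
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.zeros(ng)
    s_idx = (ii + jj).astype(int) - 2
    d_idx = np.abs(ii - jj).astype(int)
    np.add.at(p_sum, s_idx.ravel(), p.ravel())
    np.add.at(p_diff, d_idx.ravel(), p.ravel())

    contrast = float((((ii - jj) ** 2) * p).sum())
    if sig_x * sig_y > 0:
        correlation = float(
            (((ii - mu_x) * (jj - mu_y) * p).sum()) / (sig_x * sig_y))
    else:
        correlation = 1.0  # degenerate: a single occupied level

    da = float((k_diff * p_diff).sum())
    hxy = float(-xlog2(p).sum())
    hx = float(-xlog2(px).sum())
    hy = float(-xlog2(py).sum())
    pxpy = np.outer(px, py)
    # only terms where p > 0 contribute to HXY1 (0 log 0 := 0)
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-xlog2(pxpy).sum())
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off_diag = d_idx > 0
    inverse_variance = float((p[off_diag] / (d_idx[off_diag] ** 2)).sum())

    return {
        "autocorrelation": float((ii * jj * p).sum()),
        "joint_average": mu_x,
        "cluster_prominence": float((((ii + jj - mu_x - mu_y) ** 4) * p).sum()),
        "cluster_shade": float((((ii + jj - mu_x - mu_y) ** 3) * p).sum()),
        "cluster_tendency": float((((ii + jj - mu_x - mu_y) ** 2) * p).sum()),
        "contrast": contrast,
        "correlation": correlation,
        "difference_average": da,
        "difference_entropy": float(-xlog2(p_diff).sum()),
        "difference_variance": float((((k_diff - da) ** 2) * p_diff).sum()),
        "joint_energy": float((p ** 2).sum()),
        "joint_entropy": hxy,
        "imc1": imc1,
        "imc2": imc2,
        "idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "inverse_variance": inverse_variance,
        "maximum_probability": float(p.max()),
        "sum_average": float((k_sum * p_sum).sum()),
        "sum_entropy": float(-xlog2(p_sum).sum()),
    }


def glcm_features(g: GLCMatrix) -> dict[str, float]:
    """The 22 texture features, averaged over offsets with pairs."""
    probs = g.probabilities
    has_pairs = g.counts.sum(axis=(1, 2)) > 0
    if not has_pairs.any():
        raise ValueError("GLCM has no co-occurring pairs at any offset")
    per_offset = [_features_one(probs[oi])
                  for oi in range(len(g.offsets)) if has_pairs[oi]]
    return {
        name: float(np.mean([f[name] for f in per_offset]))
        for name in GLCM_FEATURE_NAMES
    }
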