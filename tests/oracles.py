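"""Independent brute-force reference implementations used as oracles.

Everything here is written from the textbook definitions with explicit
loops and closed forms, deliberately sharing no code path with the
package, so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------- first-order

def percentile_linear(sorted_x, q):
    """Linear-interpolation percentile on pre-sorted data."""
    n = len(sorted_x)
    pos = (n - 1) * q / 100.0
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_x[lo] * (1 - frac) + sorted_x[hi] * frac


def firstorder_oracle(values, levels, n_bins, voxel_volume):
    x = sorted(float(v) for v in values)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    p10 = percentile_linear(x, 10)
    p25 = percentile_linear(x, 25)
    p75 = percentile_linear(x, 75)
    p90 = percentile_linear(x, 90)
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust) if robust else 0.0
    hist = [0] * n_bins
    for lv in levels:
        hist[int(lv) - 1] += 1
    p = [h / n for h in hist]
    entropy = -sum(pi * math.log2(pi) for pi in p if pi > 0)
    if sd > 0:
        skew = sum(((v - mean) / sd) ** 3 for v in x) / n
        kurt = sum(((v - mean) / sd) ** 4 for v in x) / n
    else:
        skew = kurt = 0.0
    energy = sum(v * v for v in x)
    return {
        "energy": energy,
        "total_energy": voxel_volume * energy,
        "entropy": entropy,
        "minimum": x[0],
        "percentile_10": p10,
        "percentile_90": p90,
        "maximum": x[-1],
        "mean": mean,
        "median": percentile_linear(x, 50),
        "interquartile_range": p75 - p25,
        "range": x[-1] - x[0],
        "mean_absolute_deviation": sum(abs(v - mean) for v in x) / n,
        "robust_mean_absolute_deviation":
            sum(abs(v - rmean) for v in robust) / len(robust) if robust else 0.0,
        "root_mean_squared": math.sqrt(energy / n),
        "skewness": skew,
        "kurtosis": kurt,
        "variance": var,
        "uniformity": sum(pi * pi for pi in p),
    }


# ---------------------------------------------------------------------- GLCM

def glcm_counts_oracle(levels, mask, offset, n_bins):
    """Triple-loop symmetric pair counting for one offset."""
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)
    nx, ny, nz = levels.shape
    dx, dy, dz = offset
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                a, b, c = i + dx, j + dy, k + dz
                if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz \
                        and mask[a, b, c]:
                    u, v = levels[i, j, k] - 1, levels[a, b, c] - 1
                    counts[u, v] += 1
                    counts[v, u] += 1
    return counts


def glcm_features_oracle(P):
    """All 22 texture features by explicit double loops over one
    normalized co-occurrence matrix."""
    ng = P.shape[0]
    idx = range(1, ng + 1)
    px = [sum(P[i - 1, j - 1] for j in idx) for i in idx]
    py = [sum(P[i - 1, j - 1] for i in idx) for j in idx]
    mu_x = sum(i * px[i - 1] for i in idx)
    mu_y = sum(j * py[j - 1] for j in idx)
    sig_x = math.sqrt(sum((i - mu_x) ** 2 * px[i - 1] for i in idx))
    sig_y = math.sqrt(sum((j - mu_y) ** 2 * py[j - 1] for j in idx))
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(0, ng)}
    for i in idx:
        for j in idx:
            p_sum[i + j] += P[i - 1, j - 1]
            p_diff[abs(i - j)] += P[i - 1, j - 1]

    def l2(v):
        return math.log2(v) if v > 0 else 0.0

    hxy = -sum(P[i - 1, j - 1] * l2(P[i - 1, j - 1])
               for i in idx for j in idx)
    hx = -sum(px[i - 1] * l2(px[i - 1]) for i in idx)
    hy = -sum(py[j - 1] * l2(py[j - 1]) for j in idx)
    hxy1 = -sum(P[i - 1, j - 1] * l2(px[i - 1] * py[j - 1])
                for i in idx for j in idx)
    hxy2 = -sum(px[i - 1] * py[j - 1] * l2(px[i - 1] * py[j - 1])
                for i in idx for j in idx)
    da = sum(k * v for k, v in p_diff.items())
    if sig_x * sig_y > 0:
        corr = sum((i - mu_x) * (j - mu_y) * P[i - 1, j - 1]
                   for i in idx for j in idx) / (sig_x * sig_y)
    else:
        corr = 1.0
    denom = max(hx, hy)
    return {
        "autocorrelation": sum(i * j * P[i - 1, j - 1]
                               for i in idx for j in idx),
        "joint_average": mu_x,
        "cluster_prominence": sum((i + j - mu_x - mu_y) ** 4 * P[i - 1, j - 1]
                                  for i in idx for j in idx),
        "cluster_shade": sum((i + j - mu_x - mu_y) ** 3 * P[i - 1, j - 1]
                             for i in idx for j in idx),
        "cluster_tendency": sum((i + j - mu_x - mu_y) ** 2 * P[i - 1, j - 1]
                                for i in idx for j in idx),
        "contrast": sum((i - j) ** 2 * P[i - 1, j - 1]
                        for i in idx for j in idx),
        "correlation": corr,
        "difference_average": da,
        "difference_entropy": -sum(v * l2(v) for v in p_diff.values()),
        "difference_variance": sum((k - da) ** 2 * v
                                   for k, v in p_diff.items()),
        "joint_energy": sum(P[i - 1, j - 1] ** 2 for i in idx for j in idx),
        "joint_entropy": hxy,
        "imc1": (hxy - hxy1) / denom if denom > 0 else 0.0,
        "imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "idm": sum(P[i - 1, j - 1] / (1 + (i - j) ** 2)
                   for i in idx for j in idx),
        "idmn": sum(P[i - 1, j - 1] / (1 + ((i - j) / ng) ** 2)
                    for i in idx for j in idx),
        "id": sum(P[i - 1, j - 1] / (1 + abs(i - j))
                  for i in idx for j in idx),
        "idn": sum(P[i - 1, j - 1] / (1 + abs(i - j) / ng)
                   for i in idx for j in idx),
        "inverse_variance": sum(P[i - 1, j - 1] / (i - j) ** 2
                                for i in idx for j in idx if i != j),
        "maximum_probability": max(P[i - 1, j - 1]
                                   for i in idx for j in idx),
        "sum_average": sum(k * v for k, v in p_sum.items()),
        "sum_entropy": -sum(v * l2(v) for v in p_sum.values()),
    }


# --------------------------------------------------------------------- shape

def shape_oracle(mask, spacing):
    """Moment/extent shape quantities by explicit loops (no mesh)."""
    coords = [
        (i * spacing[0], j * spacing[1], k * spacing[2])
        for i in range(mask.shape[0])
        for j in range(mask.shape[1])
        for k in range(mask.shape[2])
        if mask[i, j, k]
    ]
    n = len(coords)
    cx = sum(c[0] for c in coords) / n
    cy = sum(c[1] for c in coords) / n
    cz = sum(c[2] for c in coords) / n
    cov = np.zeros((3, 3))
    for (x, y, z) in coords:
        d = np.array([x - cx, y - cy, z - cz])
        cov += np.outer(d, d)
    cov /= n
    eig = sorted(np.linalg.eigvalsh(cov), reverse=True)
    eig = [max(e, 0.0) for e in eig]

    def max_dist(points):
        best = 0.0
        for p, q in itertools.combinations(points, 2):
            best = max(best, math.dist(p, q))
        return best

    def max_dist_plane(drop):
        best = 0.0
        planes = sorted({c[drop] for c in coords})
        for value in planes:
            pts = [tuple(v for a, v in enumerate(c) if a != drop)
                   for c in coords if c[drop] == value]
            best = max(best, max_dist(pts))
        return best

    return {
        "voxel_volume": n * spacing[0] * spacing[1] * spacing[2],
        "major_axis_length": 4.0 * math.sqrt(eig[0]),
        "minor_axis_length": 4.0 * math.sqrt(eig[1]),
        "least_axis_length": 4.0 * math.sqrt(eig[2]),
        "elongation": math.sqrt(eig[1] / eig[0]) if eig[0] > 0 else 1.0,
        "flatness": math.sqrt(eig[2] / eig[0]) if eig[0] > 0 else 1.0,
        "maximum_3d_diameter": max_dist(coords),
        "maximum_2d_diameter_slice": max_dist_plane(2),
        "maximum_2d_diameter_row": max_dist_plane(0),
        "maximum_2d_diameter_column": max_dist_plane(1),
    }


def mesh_oracle(verts, faces):
    """Triangle-mesh area and enclosed volume via trimesh."""
    import trimesh

    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return float(mesh.area), float(abs(mesh.volume))


# ------------------------------------------------------------ clustering etc.

def pam_exhaustive_cost(D, k):
    """Optimal k-medoid cost by exhaustive search over medoid sets."""
    n = D.shape[0]
    best = math.inf
    for medoids in itertools.combinations(range(n), k):
        cost = sum(min(D[m, j] for m in medoids) for j in range(n))
        best = min(best, cost)
    return best


def pam_cost(D, labels, medoids):
    return sum(D[medoids[labels[j]], j] for j in range(D.shape[0]))


def spearman_oracle(a, b):
    """Rank-then-Pearson correlation for two profiles."""
    ra = sps.rankdata(a)
    rb = sps.rankdata(b)
    return float(sps.pearsonr(ra, rb).statistic)


def fisher_2x2_oracle(a, b, c, d):
    """Two-sided Fisher p: sum of hypergeometric point probabilities
    no larger than the observed one."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    rv = sps.hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(col1, row1) + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


def km_oracle(times, events):
    """Hand product-limit estimator: returns (event_times, S(t))."""
    order = np.argsort(times)
    times = np.asarray(times)[order]
    events = np.asarray(events)[order]
    s = 1.0
    out_t, out_s = [], []
    at_risk = len(times)
    for t in sorted(set(times)):
        d = int(((times == t) & (events == 1)).sum())
        c = int(((times == t) & (events == 0)).sum())
        if d > 0:
            s *= 1.0 - d / at_risk
            out_t.append(t)
            out_s.append(s)
        at_risk -= d + c
    return out_t, out_s


def micro_auc_concordance_oracle(proba, y, classes):
    """Pooled one-vs-rest pairwise concordance (ties count 1/2)."""
    scores, truths = [], []
    for ci, c in enumerate(classes):
        for s, t in zip(proba[:, ci], y):
            scores.append(s)
            truths.append(1 if t == c else 0)
    pos = [s for s, t in zip(scores, truths) if t == 1]
    neg = [s for s, t in zip(scores, truths) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
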