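"""Consensus clustering of radiomics features and cross-cohort
reproducibility.

Subtype discovery follows the resampled consensus approach: the
z-scored feature table is repeatedly subsampled (80% of samples and
80% of features, without replacement), each subsample is clustered by
partitioning-around-medoids (PAM) over Spearman distance for every
candidate k, and the pairwise consensus value of two samples is the
fraction of their co-sampled runs in which they co-clustered. The
number of clusters is chosen where the area under the empirical CDF
of consensus values stops growing appreciably (relative delta-area
rule), and final labels come from average-linkage hierarchical
clustering of the consensus matrix.

Reproducibility of a clustering in a second cohort is quantified by
the in-group proportion (IGP): validation samples are assigned to the
discovery centroid with the highest Spearman correlation, and IGP of
a group is the percentage of its assigned samples whose nearest
validation neighbour (again by Spearman correlation) is assigned to
the same group — 100% when the clusters are reproduced perfectly,
near chance level (100/k) for arbitrary labels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.decomposition import PCA

__all__ = [
    "ConsensusResult", "SubtypeModel", "IGPReport",
    "zscore_features", "spearman_distance", "pam_cluster",
    "consensus_cluster", "select_optimal_k", "final_labels",
    "compute_centroids", "igp_from_labels", "igp_validate",
    "pca_contributions",
]


@dataclass
class ConsensusResult:
    """Per-k consensus matrices and the optimal-k decision trail."""

    k_range: tuple[int, ...]
    consensus: dict[int, np.ndarray]
    areas: dict[int, float]
    delta_areas: dict[int, float]
    optimal_k: int
    labels: np.ndarray
    sample_ids: list[str]
    flags: list[str] = field(default_factory=list)

    def cdf(self, k: int, n_bins: int = 100):
        """Empirical CDF of the upper-triangle consensus values."""
        vals = _upper_triangle(self.consensus[k])
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        counts, _ = np.histogram(vals, bins=edges)
        return edges[1:], np.cumsum(counts) / len(vals)


@dataclass
class SubtypeModel:
    """Cluster centroids in z-space plus the scaling to reach it."""

    centroids: pd.DataFrame   # clusters x features (z-scored space)
    scaling: pd.DataFrame     # features x (mean, sd)

    @property
    def feature_names(self) -> list[str]:
        return list(self.centroids.columns)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Z-score an external feature table with the stored scaling."""
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise ValueError(f"validation table lacks features: {missing[:5]}"
                             f"{'...' if len(missing) > 5 else ''}")
        sub = table[self.feature_names]
        return (sub - self.scaling["mean"]) / self.scaling["sd"]


@dataclass
class IGPReport:
    """Per-group in-group proportion of a validation cohort (percent)."""

    per_group_igp: dict
    assigned_labels: np.ndarray


def zscore_features(table: pd.DataFrame,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score columns (sample SD); drop zero-variance columns.

    Returns the scaled table and a ``features x (mean, sd)`` scaling
    frame for re-applying the transform to a validation cohort.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 samples to z-score")
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all feature columns have zero variance")
    dropped = list(table.columns[~keep])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance features: "
                      f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}")
    scaled = (table.loc[:, keep] - mean[keep]) / sd[keep]
    scaling = pd.DataFrame({"mean": mean[keep], "sd": sd[keep]})
    return scaled, scaling


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return rankdata(X, axis=1)


def spearman_distance(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise ``1 - Spearman rho`` between sample feature profiles.

    Range [0, 2]; identical rank profiles give 0, exactly reversed
    ranks give 2. A constant profile has undefined correlation: its
    off-diagonal distances are set to 1 (with a warning).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features per sample")
    ranks = _rank_rows(X)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant profiles; "
                      "their Spearman distance is set to 1")
        sd = np.where(constant, 1.0, sd)
    z = (ranks - ranks.mean(axis=1, keepdims=True)) / sd[:, None]
    corr = z @ z.T / X.shape[1]
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def pam_cluster(distance: np.ndarray, k: int, seed: int | None = None,
                max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids on a precomputed distance matrix.

    Classic BUILD + SWAP: greedy medoid initialization, then repeated
    single best (medoid, non-medoid) exchanges while the total
    distance to nearest medoids decreases. Fully deterministic — ties
    break toward the lowest index — so ``seed`` is accepted only for
    interface symmetry with the stochastic steps.

    Returns ``(labels, medoids)`` with labels in ``0..k-1`` numbered
    by medoid order.
    """
    D = np.asarray(distance, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance must be square")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")

    medoids = [int(np.argmin(D.sum(axis=1)))]
    dnear = D[medoids[0]].copy()
    while len(medoids) < k:
        gain = np.minimum(D, dnear[None, :]).sum(axis=1)
        gain[medoids] = np.inf
        c = int(np.argmin(gain))
        medoids.append(c)
        np.minimum(dnear, D[c], out=dnear)
    medoids = np.array(medoids)

    for _ in range(max_iter):
        Dm = D[medoids]                       # k x n
        order = np.argsort(Dm, axis=0, kind="stable")
        nearest = order[0]
        cols = np.arange(n)
        d1 = Dm[nearest, cols]
        d2 = Dm[order[1], cols] if k > 1 else np.full(n, np.inf)

        cand = np.setdiff1d(cols, medoids)
        if len(cand) == 0:
            break
        Dc = D[cand]                          # c x n
        base = np.minimum(Dc, d1[None, :]) - d1[None, :]
        base_sum = base.sum(axis=1)
        delta = np.empty((len(cand), k))
        for mi in range(k):
            jm = nearest == mi
            swapped = np.minimum(Dc[:, jm], d2[jm][None, :]) - d1[jm][None, :]
            delta[:, mi] = base_sum - base[:, jm].sum(axis=1) \
                + swapped.sum(axis=1)
        ci, mi = np.unravel_index(int(np.argmin(delta)), delta.shape)
        if delta[ci, mi] < -1e-12:
            medoids[mi] = cand[ci]
        else:
            break

    medoids = np.sort(medoids)
    labels = np.argmin(D[medoids], axis=0)
    return labels, medoids


def _upper_triangle(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def _cdf_area(M: np.ndarray, n_bins: int = 100) -> float:
    """Area under the empirical CDF of consensus values (histogram
    approximation on a fixed [0, 1] grid, Monti's convention)."""
    vals = _upper_triangle(M)
    counts, edges = np.histogram(vals, bins=np.linspace(0, 1, n_bins + 1))
    cdf = np.cumsum(counts) / len(vals)
    return float((cdf * np.diff(edges)).sum())


def consensus_cluster(table: pd.DataFrame,
                      k_range=range(2, 9), reps: int = 500,
                      p_item: float = 0.8, p_feature: float = 0.8,
                      seed: int = 0,
                      delta_threshold: float = 0.10) -> ConsensusResult:
    """Monti consensus clustering with a PAM/Spearman inner loop.

    Every repetition draws ``ceil(p_item * n)`` samples and
    ``ceil(p_feature * p)`` features without replacement (one draw
    shared by all k), recomputes the Spearman distance on the
    subsample and runs PAM per k. ``consensus[k][i, j]`` is the
    co-clustering count divided by the co-sampling count; pairs never
    co-sampled get 0 with a warning (vanishingly rare at 80%
    subsampling and ≥ 100 repetitions).
    """
    k_range = tuple(k_range)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n, p = table.shape
    if n <= max(k_range):
        raise ValueError(f"need more samples ({n}) than max k "
                         f"({max(k_range)})")
    X = np.asarray(table, dtype=float)
    rng = np.random.default_rng(seed)
    n_item = math.ceil(p_item * n)
    n_feat = math.ceil(p_feature * p)

    together = {k: np.zeros((n, n)) for k in k_range}
    co_sampled = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # subsamples may drop variance
        for _ in range(reps):
            items = np.sort(rng.choice(n, n_item, replace=False))
            feats = rng.choice(p, n_feat, replace=False)
            block = np.ix_(items, items)
            co_sampled[block] += 1
            D = spearman_distance(X[np.ix_(items, feats)])
            for k in k_range:
                labels, _ = pam_cluster(D, k)
                together[k][block] += labels[:, None] == labels[None, :]

    flags: list[str] = []
    never = (co_sampled == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        flags.append(f"{int(never.sum()) // 2} sample pairs never co-sampled"
                     " (consensus set to 0)")
        warnings.warn(flags[-1])

    consensus: dict[int, np.ndarray] = {}
    areas: dict[int, float] = {}
    for k in k_range:
        M = np.zeros((n, n))
        np.divide(together[k], co_sampled, out=M, where=co_sampled > 0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0
        consensus[k] = M
        areas[k] = _cdf_area(M)

    delta_areas: dict[int, float] = {}
    ks = sorted(k_range)
    for i, k in enumerate(ks):
        if i == 0:
            delta_areas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            delta_areas[k] = (areas[k] - prev) / prev if prev > 0 else 0.0

    result = ConsensusResult(k_range, consensus, areas, delta_areas,
                             optimal_k=ks[0], labels=np.zeros(n, dtype=int),
                             sample_ids=[str(i) for i in table.index],
                             flags=flags)
    result.optimal_k = select_optimal_k(result, threshold=delta_threshold)
    result.labels = final_labels(consensus[result.optimal_k],
                                 result.optimal_k)
    return result


def select_optimal_k(result: ConsensusResult,
                     threshold: float = 0.10) -> int:
    """Relative delta-area elbow rule.

    Returns the largest tested k whose relative increase in CDF area
    is at least ``threshold`` — the last k before further splits stop
    adding consensus structure. Flags the low-confidence edge cases
    (no k above threshold, or every k above it).
    """
    ks = sorted(result.k_range)
    above = [k for k in ks if result.delta_areas[k] >= threshold]
    if not above:
        result.flags.append("no k exceeded the delta-area threshold; "
                            "falling back to the smallest k (low confidence)")
        return ks[0]
    if len(above) == len(ks):
        result.flags.append("delta-area above threshold for every tested k; "
                            "returning max(k_range) (low confidence)")
    return above[-1]


def final_labels(consensus: np.ndarray, k: int) -> np.ndarray:
    """Cut an average-linkage tree of ``1 - consensus`` into k groups."""
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust") - 1


def compute_centroids(scaled: pd.DataFrame, labels: np.ndarray,
                      scaling: pd.DataFrame) -> SubtypeModel:
    """Per-cluster mean z-scored feature vectors."""
    labels = np.asarray(labels)
    if len(labels) != len(scaled):
        raise ValueError("labels length must match table")
    centroids = scaled.groupby(labels).mean()
    return SubtypeModel(centroids=centroids, scaling=scaling)


def _spearman_corr_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Spearman correlation between every row of A and every row of B."""
    ra = _rank_rows(A)
    rb = _rank_rows(B)

    def standardize(R):
        sd = R.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (R - R.mean(axis=1, keepdims=True)) / sd

    return standardize(ra) @ standardize(rb).T / A.shape[1]


def igp_from_labels(profiles: np.ndarray, labels: np.ndarray) -> dict:
    """In-group proportion of given labels on given (z-scored) profiles.

    For each group: the percentage of its samples whose nearest
    neighbour by Spearman correlation (excluding self) carries the
    same label. With labels assigned at random the expectation is the
    chance level (~100/k for balanced groups); 100 when groups are
    perfectly separated.
    """
    profiles = np.asarray(profiles, dtype=float)
    labels = np.asarray(labels)
    corr_nn = _spearman_corr_rows(profiles, profiles)
    np.fill_diagonal(corr_nn, -np.inf)
    nearest = np.argmax(corr_nn, axis=1)
    per_group = {}
    for name in pd.unique(labels):
        members = labels == name
        if not members.any():
            per_group[name] = float("nan")
            continue
        per_group[name] = 100.0 * float(
            (labels[nearest[members]] == name).mean())
    return per_group


def igp_validate(validation: pd.DataFrame, model: SubtypeModel) -> IGPReport:
    """In-group proportion of a validation cohort against a model.

    Samples are assigned to the centroid with the highest Spearman
    correlation (ties to the lowest cluster index); IGP of a group is
    the percentage of its assigned samples whose nearest validation
    neighbour (highest Spearman correlation, excluding self) shares
    the group. Groups to which nothing was assigned report NaN.
    """
    Z = np.asarray(model.transform(validation), dtype=float)
    C = np.asarray(model.centroids, dtype=float)
    group_names = list(model.centroids.index)

    corr_to_centroids = _spearman_corr_rows(Z, C)
    assigned = np.argmax(corr_to_centroids, axis=1)
    labels = np.asarray([group_names[a] for a in assigned])

    per_group = igp_from_labels(Z, labels)
    # report every model group, including ones that attracted nothing
    for name in group_names:
        per_group.setdefault(name, float("nan"))
    return IGPReport(per_group_igp=per_group, assigned_labels=labels)


def pca_contributions(scaled: pd.DataFrame, n_components: int | None = None):
    """PCA of the z-scored table: loadings, explained variance and
    per-feature contribution (%) to each component.

    Returns ``(loadings, explained_variance_ratio, contributions)``
    with loadings and contributions as components x features frames.
    """
    n_components = n_components or min(scaled.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(np.asarray(scaled, dtype=float))
    comp_names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    loadings = pd.DataFrame(pca.components_, index=comp_names,
                            columns=scaled.columns)
    contrib = 100.0 * loadings ** 2
    contrib = contrib.div(contrib.sum(axis=1), axis=0)  # fractions per PC
    contrib *= 100.0
    return loadings, pca.explained_variance_ratio_, contrib
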