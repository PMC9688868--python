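"""Gene-expression bridge: predict imaging subtypes from expression
and compare survival across (predicted) subtypes.

Subtype-specific genes are selected by per-gene one-way ANOVA on
log2(count + 1) values with Benjamini-Hochberg control; a random
forest (2000 trees by default) trained on those genes predicts the
imaging subtype of samples that have no imaging, and performance is
summarized by the micro-averaged multi-class ROC AUC (one-vs-rest
decisions pooled across classes into a single curve). Survival is
compared across groups by Kaplan-Meier curves and the k-group
log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import label_binarize
from statsmodels.stats.multitest import multipletests

__all__ = ["SubtypeClassifier", "select_subtype_genes",
           "train_subtype_classifier", "predict_subtypes", "micro_auc",
           "km_logrank"]


def _log_transform(expr: pd.DataFrame) -> pd.DataFrame:
    return np.log2(expr.astype(float) + 1.0)


def select_subtype_genes(expr: pd.DataFrame, labels, alpha: float = 0.05,
                         ) -> pd.DataFrame:
    """Per-gene one-way ANOVA on log2(x+1) expression across subtypes.

    Returns a frame indexed by gene id with columns ``F, p, p_adj``
    (Benjamini-Hochberg), restricted to genes with adjusted p < alpha
    and sorted by p. Constant genes are skipped; their count is in
    ``result.attrs["n_skipped_constant"]``.
    """
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ValueError("gene selection needs >= 2 subtype groups")
    if expr.shape[1] != len(labels):
        raise ValueError("labels length must match number of samples")
    X = _log_transform(expr).to_numpy()
    groups = [X[:, labels == g] for g in sorted(set(labels))]
    variable = X.std(axis=1) > 0
    n_skipped = int((~variable).sum())

    F, p = sps.f_oneway(*[g[variable] for g in groups], axis=1)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    result = pd.DataFrame({"F": F, "p": p, "p_adj": p_adj},
                          index=expr.index[variable])
    result = result[reject].sort_values("p")
    result.attrs["n_skipped_constant"] = n_skipped
    return result


@dataclass
class SubtypeClassifier:
    """A trained gene-expression subtype classifier."""

    selected_genes: list[str]
    forest: RandomForestClassifier
    class_order: list
    n_trees: int
    seed: int

    @property
    def feature_importances(self) -> pd.Series:
        return pd.Series(self.forest.feature_importances_,
                         index=self.selected_genes)


def train_subtype_classifier(expr: pd.DataFrame, labels, genes,
                             n_trees: int = 2000, seed: int = 0,
                             ) -> SubtypeClassifier:
    """Random forest on log2(x+1) expression of the selected genes.

    Default forest parameters except the number of trees (2000);
    deterministic for a given seed.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValueError(f"expression lacks selected genes: {missing[:5]}")
    X = _log_transform(expr.loc[genes]).to_numpy().T
    y = np.asarray(labels)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X, y)
    return SubtypeClassifier(genes, forest, list(forest.classes_),
                             n_trees, seed)


def predict_subtypes(model: SubtypeClassifier, expr_new: pd.DataFrame,
                     ) -> tuple[np.ndarray, pd.DataFrame]:
    """Predict subtype labels and class probabilities for new samples.

    ``expr_new`` must contain every selected gene (missing genes raise
    with the offending ids). Probabilities sum to 1 per sample.
    """
    missing = [g for g in model.selected_genes if g not in expr_new.index]
    if missing:
        raise ValueError(
            f"expression lacks {len(missing)} selected genes: {missing[:5]}"
            f"{'...' if len(missing) > 5 else ''}")
    X = _log_transform(expr_new.loc[model.selected_genes]).to_numpy().T
    proba = model.forest.predict_proba(X)
    labels = np.asarray(model.class_order)[np.argmax(proba, axis=1)]
    proba_df = pd.DataFrame(proba, index=expr_new.columns,
                            columns=model.class_order)
    return labels, proba_df


def micro_auc(probabilities: pd.DataFrame | np.ndarray, true_labels,
              ) -> float:
    """Micro-averaged multi-class ROC AUC.

    True labels are one-vs-rest binarized, pooled across classes with
    the matching probability scores, and a single ROC curve is
    integrated (trapezoidal). Invariant to monotone transforms of the
    scores.
    """
    if isinstance(probabilities, pd.DataFrame):
        classes = list(probabilities.columns)
        scores = probabilities.to_numpy()
    else:
        scores = np.asarray(probabilities, dtype=float)
        classes = sorted(set(np.asarray(true_labels).tolist()))
    y = label_binarize(np.asarray(true_labels), classes=classes)
    if y.shape[1] == 1:  # binary case: binarize yields one column
        y = np.column_stack([1 - y[:, 0], y[:, 0]])
    return float(roc_auc_score(y.ravel(), scores.ravel()))


@dataclass
class KMResult:
    curves: dict                 # group -> survival-function DataFrame
    statistic: float             # log-rank chi-square, k-1 df
    pvalue: float


def km_logrank(survival: pd.DataFrame, group_col: str = "group",
               time_col: str = "time", event_col: str = "event") -> KMResult:
    """Product-limit curves per group and the k-group log-rank test."""
    for col in (group_col, time_col, event_col):
        if col not in survival.columns:
            raise ValueError(f"survival table lacks column {col!r}")
    if (survival[time_col] <= 0).any():
        raise ValueError("survival times must be positive")
    curves = {}
    for g, sub in survival.groupby(group_col):
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=str(g))
        curves[g] = kmf.survival_function_
    res = multivariate_logrank_test(survival[time_col],
                                    survival[group_col],
                                    survival[event_col])
    return KMResult(curves, float(res.test_statistic), float(res.p_value))
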