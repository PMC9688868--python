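"""Subtype-level statistics: feature differences and clinical
associations.

Thin, convention-fixing wrappers over scipy/statsmodels: one-way
ANOVA and Tukey HSD for k-group feature comparisons, two-sided
Student's t (pooled variance; Welch by flag) for two groups,
t-distribution 95% confidence intervals of feature means, and a
chi-squared / Fisher switch for contingency tables (Fisher whenever
any expected count falls below 5, the standard rule; the method that
actually ran is always reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["anova_oneway", "tukey_hsd", "t_test", "mean_ci95",
           "association_test"]


def _groups(values, labels) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    return [values[labels == g] for g in pd.unique(labels)], list(pd.unique(labels))


def anova_oneway(values, labels) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA; returns (F, p)."""
    groups, names = _groups(values, labels)
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 samples each")
    res = sps.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def tukey_hsd(values, labels) -> pd.DataFrame:
    """Tukey's honest-significant-difference pairwise comparisons.

    Returns a frame with one row per unordered group pair:
    ``group_a, group_b, mean_diff, p_adj`` (family-wise adjusted via
    the studentized range).
    """
    groups, names = _groups(values, labels)
    if len(groups) < 2:
        raise ValueError("Tukey HSD needs >= 2 groups")
    res = sps.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append({
                "group_a": names[i],
                "group_b": names[j],
                "mean_diff": float(groups[i].mean() - groups[j].mean()),
                "p_adj": float(res.pvalue[i, j]),
            })
    return pd.DataFrame(rows)


def t_test(values_a, values_b, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test; Student (pooled variance) by
    default, Welch with ``welch=True``. Returns (t, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def mean_ci95(values) -> tuple[float, float, float]:
    """Mean with t-distribution 95% CI: ``mean ± t(0.975, n-1) * se``."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("CI needs at least 2 values")
    mean = float(x.mean())
    se = float(x.std(ddof=1) / np.sqrt(n))
    half = float(sps.t.ppf(0.975, n - 1)) * se
    return mean, mean - half, mean + half


@dataclass
class AssociationResult:
    statistic: float
    pvalue: float
    method: str           # "chi2" | "fisher" | "fisher_mc"


def association_test(table, min_expected: float = 5.0,
                     mc_reps: int = 20000, seed: int = 0,
                     ) -> AssociationResult:
    """Independence test for a groups x categories contingency table.

    Pearson's chi-squared when every expected count strictly exceeds
    ``min_expected``; otherwise Fisher's exact test — the closed-form
    hypergeometric version on 2x2 tables, and for larger sparse
    tables a conditional Monte-Carlo version (tables drawn with the
    observed margins; p = proportion at most as probable as the
    observed table). The ``method`` field reports which ran.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a 2D nonnegative count matrix")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has an empty row or column")

    chi2, p, _, expected = sps.chi2_contingency(t, correction=False)
    if (expected > min_expected).all():
        return AssociationResult(float(chi2), float(p), "chi2")
    if t.shape == (2, 2):
        res = sps.fisher_exact(t, alternative="two-sided")
        return AssociationResult(float(res[0]), float(res[1]), "fisher")

    rng = np.random.default_rng(seed)
    dist = sps.random_table(t.sum(axis=1), t.sum(axis=0))
    log_p_obs = dist.logpmf(t)
    sims = dist.rvs(mc_reps, random_state=rng)
    log_p_sim = dist.logpmf(sims)
    # +1 correction keeps the MC p-value valid (never exactly 0)
    count = int((log_p_sim <= log_p_obs + 1e-9).sum())
    pval = (count + 1) / (mc_reps + 1)
    return AssociationResult(float(np.exp(log_p_obs)), float(pval),
                             "fisher_mc")
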