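"""Group-level statistics and summary reporting.

Thin, explicit wrappers around scipy.stats implementing the comparisons
used throughout: unpaired two-sample t (Welch by default), one-way ANOVA,
two-sample Kolmogorov-Smirnov, and Pearson chi-square on count tables
(without continuity correction). Results are reported as mean ± SEM with a
significance flag at p < 0.05. An opt-in Benjamini-Hochberg column is
available in the summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class GroupComparison:
    test: str  # t | anova | ks | chi2
    statistic: float
    p_value: float
    group_sizes: list[int]
    means: list[float] = field(default_factory=list)
    sems: list[float] = field(default_factory=list)
    significant: bool = False
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not math.isnan(self.p_value):
            assert 0.0 <= self.p_value <= 1.0
            self.significant = self.p_value < ALPHA


def sem(values: np.ndarray) -> float:
    """Standard error of the mean, sd/sqrt(n) with ddof=1."""
    v = np.asarray(values, float)
    return float(np.std(v, ddof=1) / math.sqrt(v.size)) if v.size > 1 else math.nan


def compare_groups(a, b, test: str = "t", welch: bool = True) -> GroupComparison:
    """Two-group comparison by unpaired t-test or two-sample K-S test."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if test == "t":
        if a.size < 2 or b.size < 2:
            raise ValueError("t-test needs n >= 2 per group")
        if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
            return GroupComparison("t", math.nan, math.nan,
                                   [a.size, b.size], [float(a.mean()), float(b.mean())],
                                   [sem(a), sem(b)], flags=["zero_variance"])
        stat, p = sps.ttest_ind(a, b, equal_var=not welch)
    elif test == "ks":
        if a.size < 1 or b.size < 1:
            raise ValueError("K-S test needs n >= 1 per group")
        stat, p = sps.ks_2samp(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(test, float(stat), float(p), [a.size, b.size],
                           [float(a.mean()), float(b.mean())], [sem(a), sem(b)])


def anova_oneway(*groups) -> GroupComparison:
    """One-way ANOVA over >= 2 groups (F statistic and p)."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    gs = [np.asarray(g, float) for g in groups]
    if any(g.size < 2 for g in gs):
        raise ValueError("every ANOVA group needs n >= 2")
    if all(np.std(g) == 0 for g in gs):
        eq = all(float(g.mean()) == float(gs[0].mean()) for g in gs)
        return GroupComparison("anova", 0.0 if eq else math.inf,
                               math.nan, [g.size for g in gs],
                               [float(g.mean()) for g in gs],
                               [sem(g) for g in gs], flags=["zero_within_variance"])
    stat, p = sps.f_oneway(*gs)
    return GroupComparison("anova", float(stat), float(p),
                           [g.size for g in gs],
                           [float(g.mean()) for g in gs], [sem(g) for g in gs])


def chi_square_ratio(table) -> GroupComparison:
    """Pearson chi-square on a groups x categories count table, without
    continuity correction; expected counts from the margins."""
    tab = np.asarray(table, float)
    if tab.ndim != 2 or np.any(tab < 0):
        raise ValueError("need a 2-D table of non-negative counts")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    res = sps.chi2_contingency(tab, correction=False)
    return GroupComparison("chi2", float(res.statistic), float(res.pvalue),
                           [int(n) for n in tab.sum(axis=1)])


def summary_table(
    metrics: pd.DataFrame,
    group_col: str = "genotype",
    value_cols: list[str] | None = None,
    test: str = "t",
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """One row per metric: group means ± SEM, n, test statistic and p.

    ``metrics`` is a tidy per-cell table (one row per cell) with a grouping
    column and numeric metric columns. NaN cells are dropped per metric.
    ``bh_adjust`` adds a Benjamini-Hochberg adjusted-p column (opt-in; no
    multiple-testing correction by default)."""
    if group_col not in metrics.columns:
        raise ValueError(f"grouping column {group_col!r} missing")
    groups = list(pd.unique(metrics[group_col]))
    if len(groups) != 2:
        raise ValueError("summary_table compares exactly two groups")
    if value_cols is None:
        value_cols = [c for c in metrics.columns
                      if c != group_col and pd.api.types.is_numeric_dtype(metrics[c])]
    rows = []
    for col in value_cols:
        a = metrics.loc[metrics[group_col] == groups[0], col].dropna().to_numpy()
        b = metrics.loc[metrics[group_col] == groups[1], col].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        cmp = compare_groups(a, b, test=test)
        rows.append({
            "metric": col,
            f"mean_{groups[0]}": cmp.means[0], f"sem_{groups[0]}": cmp.sems[0],
            f"n_{groups[0]}": a.size,
            f"mean_{groups[1]}": cmp.means[1], f"sem_{groups[1]}": cmp.sems[1],
            f"n_{groups[1]}": b.size,
            "test": cmp.test, "statistic": cmp.statistic, "p": cmp.p_value,
            "significant": cmp.significant,
        })
    out = pd.DataFrame(rows)
    if bh_adjust and len(out):
        out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        k = m - rank_from_top
        running = min(running, p[i] * m / k)
        adj[i] = running
    return adj
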