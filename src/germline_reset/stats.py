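"""Rank-based group comparisons used across the pipeline.

Thin wrappers over scipy's Mann-Whitney/Wilcoxon rank-sum and Kruskal-Wallis
tests, a hand-written Dunn's post hoc z-test (tie-corrected), and Holm
correction for pairwise families.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def _check_groups(groups: dict, min_size: int = 1) -> dict:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < min_size:
            raise ValueError(f"group {name!r} has fewer than {min_size} values")
        out[name] = arr
    return out


def mann_whitney(x, y, alternative: str = "two-sided") -> float:
    """Two-sided (by default) Mann-Whitney U p-value, exact when tie-free
    and small."""
    res = sps.mannwhitneyu(x, y, alternative=alternative)
    return float(res.pvalue)


def pairwise_wilcoxon(groups: dict, correction: str = "holm") -> pd.DataFrame:
    """Pairwise rank-sum tests between independent groups (the R
    ``pairwise.wilcox.test`` convention), Holm-corrected."""
    groups = _check_groups(groups, min_size=2)
    rows = []
    for a, b in combinations(groups, 2):
        rows.append((a, b, mann_whitney(groups[a], groups[b])))
    df = pd.DataFrame(rows, columns=["group1", "group2", "p_raw"])
    if len(df):
        df["p_adj"] = multipletests(df["p_raw"], method=correction)[1]
    return df


def dunn_test(groups: dict, correction: str = "holm") -> pd.DataFrame:
    """Dunn's post hoc test after Kruskal-Wallis.

    For groups i, j the statistic is
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))`` with the
    tie term ``T = sum(t^3 - t) / (12 (N - 1))`` over tied-value groups of
    size t, ranks pooled over all observations.
    """
    groups = _check_groups(groups, min_size=2)
    names = list(groups)
    pooled = np.concatenate([groups[k] for k in names])
    n = np.array([len(groups[k]) for k in names])
    N = pooled.size
    ranks = sps.rankdata(pooled)
    bounds = np.concatenate([[0], np.cumsum(n)])
    mean_ranks = {
        k: ranks[bounds[i]:bounds[i + 1]].mean() for i, k in enumerate(names)
    }
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (12.0 * (N - 1)))
    var_base = N * (N + 1) / 12.0 - tie_term

    rows = []
    for (i, a), (j, b) in combinations(enumerate(names), 2):
        se = np.sqrt(var_base * (1.0 / n[i] + 1.0 / n[j]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append((a, b, z, p))
    df = pd.DataFrame(rows, columns=["group1", "group2", "z", "p_raw"])
    if len(df):
        df["p_adj"] = multipletests(df["p_raw"], method=correction)[1]
    return df


def kruskal_dunn(groups: dict, correction: str = "holm") -> tuple[float, pd.DataFrame]:
    """Kruskal-Wallis omnibus p-value plus Dunn's pairwise table."""
    checked = _check_groups(groups, min_size=2)
    kw = sps.kruskal(*checked.values())
    return float(kw.pvalue), dunn_test(checked, correction=correction)


def compare_groups(groups: dict, design: str = "pairwise-wilcoxon") -> pd.DataFrame:
    """Dispatch for the group-comparison designs used in the analyses.

    ``pairwise-wilcoxon`` — pairwise rank-sum with Holm correction;
    ``mann-whitney`` — a single two-group rank-sum test;
    ``kruskal-dunn`` — Kruskal-Wallis followed by Dunn's test (the omnibus
    p-value is attached to every row as ``p_omnibus``).
    """
    if design == "pairwise-wilcoxon":
        return pairwise_wilcoxon(groups)
    if design == "mann-whitney":
        checked = _check_groups(groups, min_size=2)
        if len(checked) != 2:
            raise ValueError("mann-whitney design needs exactly two groups")
        (a, xa), (b, xb) = checked.items()
        p = mann_whitney(xa, xb)
        return pd.DataFrame(
            {"group1": [a], "group2": [b], "p_raw": [p], "p_adj": [p]}
        )
    if design == "kruskal-dunn":
        p_omni, table = kruskal_dunn(groups)
        table["p_omnibus"] = p_omni
        return table
    raise ValueError(f"unknown design {design!r}")
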