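"""Cell-type composition tables and pairwise proportion testing.

Mixing-associated composition shifts are assessed per cell type with
2x2 chi-square tests of equal proportions (cell type versus rest)
between every pair of donor/lane groups, Yates continuity correction
applied, and Holm adjustment across the pairs — the behaviour of the
classical pairwise proportion test with default arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

__all__ = ["CompositionTable", "composition", "pairwise_prop_tests"]


@dataclass
class CompositionTable:
    counts: pd.DataFrame  # groups x cell types, complete with zeros
    frequencies: pd.DataFrame  # row-normalized

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")


def composition(
    annotation: pd.DataFrame,
    group_col: str = "group",
    type_col: str = "cell_type",
) -> CompositionTable:
    """Cross-tabulate cells by group and cell type (zeros included)."""
    for col in (group_col, type_col):
        if col not in annotation.columns:
            raise ValueError(f"annotation lacks column {col!r}")
    counts = pd.crosstab(annotation[group_col], annotation[type_col])
    counts = counts.reindex(
        index=sorted(counts.index), columns=sorted(counts.columns), fill_value=0
    )
    counts.index.name = "group"
    counts.columns.name = "cell_type"
    freq = counts.div(counts.sum(axis=1), axis=0)
    return CompositionTable(counts=counts, frequencies=freq)


def pairwise_prop_tests(
    table: CompositionTable,
    celltype: str,
    correction: bool = True,
    adjust: str = "holm",
) -> pd.DataFrame:
    """Pairwise tests of equal cell-type proportion across groups.

    For each pair of groups the 2x2 table (cells of ``celltype`` versus
    all other cells) is tested with the chi-square test of equal
    proportions (Yates continuity correction by default); p-values are
    Holm-adjusted across the pairs.  Groups with zero cells yield NaN.
    Returns a symmetric group x group matrix with NaN diagonal.
    """
    if celltype not in table.counts.columns:
        raise KeyError(f"unknown cell type {celltype!r}")
    if table.counts.shape[0] < 2:
        raise ValueError("need at least two groups")
    groups = list(table.counts.index)
    x = table.counts[celltype]
    n = table.counts.sum(axis=1)

    pairs, raw = [], []
    for g1, g2 in combinations(groups, 2):
        if n[g1] == 0 or n[g2] == 0:
            pairs.append((g1, g2))
            raw.append(np.nan)
            continue
        obs = np.array(
            [[x[g1], n[g1] - x[g1]], [x[g2], n[g2] - x[g2]]], dtype=float
        )
        if obs.sum(axis=0).min() == 0:  # degenerate margin: no information
            pairs.append((g1, g2))
            raw.append(1.0)
            continue
        res = chi2_contingency(obs, correction=correction)
        pairs.append((g1, g2))
        raw.append(float(res.pvalue))

    raw_arr = np.asarray(raw)
    adj = np.full_like(raw_arr, np.nan)
    ok = ~np.isnan(raw_arr)
    if ok.any():
        adj[ok] = multipletests(raw_arr[ok], method=adjust)[1]

    mat = pd.DataFrame(np.nan, index=groups, columns=groups)
    for (g1, g2), p in zip(pairs, adj):
        mat.loc[g1, g2] = p
        mat.loc[g2, g1] = p
    mat.index.name = "group"
    mat.columns.name = "group"
    return mat
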