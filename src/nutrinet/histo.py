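"""Histopathology scoring statistics.

Seven distal-intestine variables (mucosal fold fusion, lamina propria,
sub-epithelial mucosa, supranuclear vacuolization, goblet cells,
eosinophilic granulocytes, total inflammatory cells), each on a
continuous 1-5 severity scale, are summed into a cumulative score per
fish. Group differences are assessed nonparametrically: Kruskal-Wallis on
midranks with tie correction, followed by Dunn's pairwise post-hoc test
(raw and BH-adjusted p reported; the adjustment choice is a reporting
convention, not a statistical necessity).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .simulate import HISTOLOGY_VARIABLES

__all__ = ["cumulative_score", "kruskal_wallis", "dunn_posthoc"]


def cumulative_score(
    table: pd.DataFrame, group_col: str = "group"
) -> tuple[pd.Series, pd.Series]:
    """Per-fish cumulative score (sum of the seven variables, range 7-35)
    and per-group means."""
    missing = [v for v in HISTOLOGY_VARIABLES if v not in table.columns]
    if missing:
        raise ValueError(f"missing histology variables: {missing}")
    per_fish = table[list(HISTOLOGY_VARIABLES)].sum(axis=1)
    per_fish.index = table["fish_id"] if "fish_id" in table else table.index
    per_fish.name = "cumulative_score"
    per_group = per_fish.groupby(table[group_col].to_numpy()).mean()
    per_group.name = "group_mean_score"
    return per_fish, per_group


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value.

    Degenerate all-identical data returns (0, 1).
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(groups, labels=None) -> pd.DataFrame:
    """Dunn's pairwise rank-based post-hoc test with tie correction.

    z_gh = (Rbar_g - Rbar_h) / sqrt((N(N+1)/12 - T) (1/n_g + 1/n_h)),
    with T = sum(t^3 - t) / (12 (N - 1)) over tie groups of the pooled
    midranks; two-sided normal p plus BH-adjusted p across pairs.
    Pairs with a zero variance term give missing values.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        var = base_var * (1.0 / len(groups[i]) + 1.0 / len(groups[j]))
        if var <= 0:
            z = p = np.nan
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "pvalue": p})
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out
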