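"""Descriptive feature-association analysis against activity categories.

This is deliberately a data exploration, not a model attribution: features
are first pruned for collinearity (greedy scan, |Spearman rho| > 0.9 drops
the later column), each surviving feature is tested for association with the
three-bin activity grouping (decreased / neutral / increased) using
Kruskal-Wallis, p-values are Benjamini-Hochberg adjusted, and the top-k
features by ascending q are selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import kruskal_wallis

__all__ = ["ImportanceResult", "prune_collinear", "rank_features"]


@dataclass(frozen=True)
class ImportanceResult:
    feature: str
    h_statistic: float
    p_value: float
    q_value: float
    rank: int
    selected: bool


def prune_collinear(features: pd.DataFrame, rho_threshold: float = 0.9
                    ) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy collinearity pruning in column order.

    Scans columns left to right; a feature is dropped when its |Spearman rho|
    with any already-kept feature exceeds ``rho_threshold`` (the earlier
    column is retained). Returns the kept column list and a drop log of
    (dropped, kept_partner, rho). Deterministic given the column order;
    permuting columns may change the kept set.
    """
    if features.shape[1] < 2:
        raise ValueError("prune_collinear requires >= 2 features")
    cols = list(features.columns)
    rho = stats.spearmanr(features.to_numpy(dtype=float)).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    kept: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for j in range(len(cols)):
        partner = next((i for i in kept if abs(rho[i, j]) > rho_threshold), None)
        if partner is None:
            kept.append(j)
        else:
            dropped.append((cols[j], cols[partner], float(rho[partner, j])))
    return [cols[i] for i in kept], dropped


def rank_features(features: pd.DataFrame, labels, k: int = 4) -> list[ImportanceResult]:
    """Rank features by Kruskal-Wallis association with activity groups.

    ``labels`` holds the three-bin categories per row. Each feature is tested
    across the non-empty groups, p-values are BH-FDR adjusted, and features
    are ranked by ascending q with ties broken by descending H. The top ``k``
    are flagged as selected. Results are returned in rank order.
    """
    from statsmodels.stats.multitest import multipletests

    labels = np.asarray(labels)
    groups = [labels == g for g in pd.unique(labels)]
    groups = [g for g in groups if g.any()]
    if len(groups) < 2:
        raise ValueError("rank_features requires >= 2 non-empty activity groups")
    names, hs, ps = [], [], []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        h, p = kruskal_wallis([x[g] for g in groups])
        names.append(col)
        hs.append(h)
        ps.append(p)
    q = multipletests(ps, method="fdr_bh")[1]
    order = sorted(range(len(names)), key=lambda i: (q[i], -hs[i], names[i]))
    results = []
    for rank, i in enumerate(order, start=1):
        results.append(ImportanceResult(
            feature=names[i], h_statistic=float(hs[i]), p_value=float(ps[i]),
            q_value=float(q[i]), rank=rank, selected=rank <= k))
    return results
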