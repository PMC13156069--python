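"""Metrics and nonparametric tests for evaluating substrate-specific scores.

Rank-based metrics dominate here because rank-preserving prediction is what
matters for pharmacogenomic triage: Spearman rho with an exact permutation
p-value at small n, per-pair rank error, Jonckheere-Terpstra ordered-trend
tests across activity bins, tie-corrected Kruskal-Wallis, and Mann-Whitney
ROC-AUC at configurable activity thresholds. Benchmarking helpers compare a
substrate-specific score against substrate-agnostic predictor tables,
per substrate, exactly as the per-substrate |rho| and mean-AUC summaries are
constructed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ActivityTable

__all__ = [
    "EvalReport",
    "spearman",
    "rmse",
    "rank_error",
    "bin_activity",
    "THREE_BIN",
    "jonckheere_test",
    "kruskal_wallis",
    "roc_auc",
    "per_substrate_benchmark",
    "per_substrate_auc_summary",
    "evaluate_scores",
]

SPEARMAN_EXACT_N = 8      # exact permutation p at or below this length
GROUP_EXACT_N = 10        # exact permutation for JT / KW at or below this total n


# ---------------------------------------------------------------------------
# correlation and error metrics
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    The two-sided p-value is exact (full permutation enumeration) for
    n <= 8 and uses the t-distribution approximation above that.
    Constant input is an error: rho is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("spearman requires n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("spearman undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= SPEARMAN_EXACT_N:
        # exact: permute one ranking over all n! arrangements
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx[list(perm)], ry)[0, 1]
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        with np.errstate(divide="ignore"):
            t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)


def rmse(pred, obs) -> float:
    """Root mean square error on the model scale."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size != obs.size:
        raise ValueError("pred and obs must have equal length")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def rank_error(pred, obs) -> np.ndarray:
    """Per-pair normalized absolute rank difference |rank(pred)-rank(obs)|/n."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size != obs.size:
        raise ValueError("pred and obs must have equal length")
    return np.abs(stats.rankdata(pred) - stats.rankdata(obs)) / pred.size


# ---------------------------------------------------------------------------
# activity binning
# ---------------------------------------------------------------------------

THREE_BIN = "three_bin"
_THRESHOLD_SCHEMES = {
    "threshold_50": (50.0, "lt"),    # reduced function: uptake < 50 is positive
    "threshold_75": (75.0, "lt"),
    "threshold_125": (125.0, "gt"),  # gain of function: uptake > 125 is positive
    "threshold_150": (150.0, "gt"),
}


def bin_activity(uptake_pct_wt: float, scheme: str = THREE_BIN,
                 inclusive: bool = False):
    """Assign an activity label to a %WT uptake value.

    ``three_bin``: 'decreased' iff uptake < 50, 'increased' iff uptake > 200,
    else 'neutral' (strict inequalities; ``inclusive=True`` switches to
    <= 50 / >= 200). Threshold schemes (``threshold_50`` ... ``threshold_150``)
    return 1 for the positive class (reduced function below 50/75, gain of
    function above 125/150) and 0 otherwise.
    """
    u = float(uptake_pct_wt)
    if scheme == THREE_BIN:
        lo, hi = (50.0, 200.0)
        if (u <= lo) if inclusive else (u < lo):
            return "decreased"
        if (u >= hi) if inclusive else (u > hi):
            return "increased"
        return "neutral"
    if scheme not in _THRESHOLD_SCHEMES:
        raise ValueError(f"unknown binning scheme {scheme!r}")
    cut, direction = _THRESHOLD_SCHEMES[scheme]
    if direction == "lt":
        return int((u <= cut) if inclusive else (u < cut))
    return int((u >= cut) if inclusive else (u > cut))


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def _group_assignments(pooled: np.ndarray, sizes: Sequence[int]):
    """Yield all distinct assignments of pooled indices into ordered groups."""
    idx = tuple(range(pooled.size))

    def rec(remaining: tuple, sizes_left: Sequence[int]):
        if len(sizes_left) == 1:
            yield (remaining,)
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield (combo,) + tail

    yield from rec(idx, list(sizes))


def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    """JT = sum over ordered group pairs of Mann-Whitney counts (ties 1/2)."""
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            jt += float((a[:, None] < b[None, :]).sum())
            jt += 0.5 * float((a[:, None] == b[None, :]).sum())
    return jt


def jonckheere_test(groups: Sequence, method: str = "auto") -> tuple[float, float]:
    """Jonckheere-Terpstra test for an increasing trend across ordered groups.

    Returns (JT, one-sided p for an increasing trend). With ``method="auto"``
    the p-value is exact (permutation enumeration) when total n <= 10 and
    otherwise comes from the continuity-corrected normal approximation with
    tie correction; ``"exact"`` / ``"asymptotic"`` force a branch. A single
    non-empty group is an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("jonckheere_test requires >= 2 non-empty ordered groups")
    sizes = [g.size for g in groups]
    n = int(sum(sizes))
    jt = _jt_statistic(groups)
    pooled = np.concatenate(groups)
    if method == "exact" or (method == "auto" and n <= GROUP_EXACT_N):
        count = 0
        total = 0
        for assign in _group_assignments(pooled, sizes):
            perm_groups = [pooled[list(ix)] for ix in assign]
            total += 1
            if _jt_statistic(perm_groups) >= jt - 1e-12:
                count += 1
        return jt, count / total
    # normal approximation with tie correction (Hollander & Wolfe)
    ni = np.array(sizes, dtype=float)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tj = tie_counts.astype(float)
    mean = (n * n - (ni ** 2).sum()) / 4.0
    t1 = (n * (n - 1) * (2 * n + 5)
          - (ni * (ni - 1) * (2 * ni + 5)).sum()
          - (tj * (tj - 1) * (2 * tj + 5)).sum()) / 72.0
    t2 = ((ni * (ni - 1) * (ni - 2)).sum() * (tj * (tj - 1) * (tj - 2)).sum()
          / (36.0 * n * (n - 1) * (n - 2)))
    t3 = ((ni * (ni - 1)).sum() * (tj * (tj - 1)).sum()
          / (8.0 * n * (n - 1)))
    var = t1 + t2 + t3
    if var <= 0:
        return jt, 1.0
    z = (jt - 0.5 - mean) / math.sqrt(var)  # continuity-corrected
    return jt, float(min(1.0, stats.norm.sf(z)))


def _kw_statistic(groups: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    offset = 0
    h = 0.0
    for g in groups:
        r = ranks[offset:offset + g.size]
        offset += g.size
        h += r.sum() ** 2 / g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - ((tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n))
    if correction == 0.0:
        return 0.0
    return h / correction


def kruskal_wallis(groups: Sequence, method: str = "auto") -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H test across >= 2 groups.

    With ``method="auto"`` p is exact (permutation enumeration) for total
    n <= 10, otherwise from the chi-squared distribution with k-1 degrees of
    freedom; ``"exact"`` / ``"asymptotic"`` force a branch. All-identical
    values give H = 0, p = 1. Empty groups are an error.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis requires >= 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("kruskal_wallis groups must be non-empty")
    n = int(sum(a.size for a in arrays))
    if n < 3:
        raise ValueError("kruskal_wallis requires total n >= 3")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        return 0.0, 1.0
    h = _kw_statistic(arrays)
    sizes = [a.size for a in arrays]
    if method == "exact" or (method == "auto" and n <= GROUP_EXACT_N):
        count = 0
        total = 0
        for assign in _group_assignments(pooled, sizes):
            perm_groups = [pooled[list(ix)] for ix in assign]
            total += 1
            if _kw_statistic(perm_groups) >= h - 1e-12:
                count += 1
        return h, count / total
    p = float(stats.chi2.sf(h, df=len(arrays) - 1))
    return h, p


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney U identity.

    AUC = U / (n1 * n0) with tied score pairs counted 1/2. Both classes must
    be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("roc_auc requires both classes present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# benchmarking across prediction methods
# ---------------------------------------------------------------------------

def _merge_method(pred: pd.DataFrame, activity: pd.DataFrame) -> pd.DataFrame:
    """Join a prediction table onto the activity table.

    Substrate-specific tables join on (gene, variant, substrate); tables
    without a substrate column (substrate-agnostic predictors) join on
    (gene, variant) and broadcast across substrates.
    """
    keys = ["gene", "variant"]
    if "substrate" in pred.columns:
        keys = keys + ["substrate"]
    return activity.merge(pred, on=keys, how="inner")


def per_substrate_benchmark(
    prediction_tables: Mapping[str, pd.DataFrame],
    table: ActivityTable,
    min_variants: int = 10,
) -> dict:
    """Per-substrate |Spearman rho| per method, with an omnibus Kruskal-Wallis.

    For every substrate with at least ``min_variants`` scored variants, the
    absolute Spearman correlation between each method's scores and the
    observed uptake is recorded. Methods' |rho| distributions are then
    compared with a Kruskal-Wallis test; per-method medians are reported.
    Prediction tables carry columns gene, variant, [substrate,] score.
    """
    if len(prediction_tables) < 2:
        raise ValueError("benchmark requires >= 2 methods")
    act = table.df
    abs_rho: dict[str, list[float]] = {m: [] for m in prediction_tables}
    for method, pred in prediction_tables.items():
        merged = _merge_method(pred, act)
        for substrate, grp in merged.groupby("substrate"):
            if grp["variant"].nunique() < min_variants:
                continue
            if np.unique(grp["score"]).size < 2:
                warnings.warn(f"method {method!r} constant on {substrate!r}; skipped")
                continue
            r, _ = spearman(grp["score"].to_numpy(), grp["uptake_pct_wt"].to_numpy())
            abs_rho[method].append(abs(r))
    nonempty = {m: v for m, v in abs_rho.items() if v}
    if not nonempty:
        raise ValueError(f"no substrate has >= {min_variants} variants")
    h, p = kruskal_wallis(list(nonempty.values())) if len(nonempty) > 1 else (0.0, 1.0)
    return {
        "abs_rho": abs_rho,
        "medians": {m: float(np.median(v)) for m, v in nonempty.items()},
        "kruskal_wallis_h": h,
        "kruskal_wallis_p": p,
    }


def per_substrate_auc_summary(
    prediction_tables: Mapping[str, pd.DataFrame],
    table: ActivityTable,
    scheme: str = "threshold_50",
    min_variants: int = 10,
) -> dict:
    """Mean per-substrate ROC-AUC (+/- SEM) per method at a threshold scheme.

    Reduced-function schemes (50/75) treat low uptake as the positive class,
    so the score sign is flipped before the AUC so that a well-behaved score
    (higher = more active) still yields AUC > 0.5. Methods constant on a
    substrate, or substrates missing a class, are excluded with a warning.
    """
    if len(prediction_tables) < 2:
        raise ValueError("benchmark requires >= 2 methods")
    act = table.df
    _, direction = _THRESHOLD_SCHEMES[scheme]
    aucs: dict[str, list[float]] = {m: [] for m in prediction_tables}
    for method, pred in prediction_tables.items():
        merged = _merge_method(pred, act)
        for substrate, grp in merged.groupby("substrate"):
            if grp["variant"].nunique() < min_variants:
                continue
            labels = np.array([bin_activity(u, scheme) for u in grp["uptake_pct_wt"]])
            scores = grp["score"].to_numpy(dtype=float)
            if direction == "lt":
                scores = -scores  # low activity scores flag the positive class
            if np.unique(scores).size < 2:
                warnings.warn(f"method {method!r} constant on {substrate!r}; skipped")
                continue
            if labels.min() == labels.max():
                warnings.warn(f"substrate {substrate!r} has one class only; skipped")
                continue
            aucs[method].append(roc_auc(scores, labels))
    out = {}
    for method, vals in aucs.items():
        if not vals:
            out[method] = {"mean_auc": float("nan"), "sem": float("nan"), "n_substrates": 0}
            continue
        v = np.asarray(vals)
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        out[method] = {"mean_auc": float(v.mean()), "sem": sem, "n_substrates": int(v.size)}
    return out


# ---------------------------------------------------------------------------
# top-level report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    spearman_rho: float
    spearman_p: float
    rmse: float
    rank_errors: np.ndarray
    per_substrate_rho: dict[str, float] = field(default_factory=dict)
    per_gene_auc: dict[str, float] = field(default_factory=dict)
    jonckheere_p: float | None = None
    binned_scores: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "rmse": self.rmse,
            "mean_rank_error": float(np.mean(self.rank_errors)),
            "per_substrate_rho": self.per_substrate_rho,
            "per_gene_auc": self.per_gene_auc,
            "jonckheere_p": self.jonckheere_p,
            "binned_scores": {k: list(map(float, v)) for k, v in self.binned_scores.items()},
        }


def evaluate_scores(scores: pd.DataFrame, table: ActivityTable,
                    min_per_substrate: int = 3) -> EvalReport:
    """Full evaluation of a score table against observed uptake.

    ``scores`` carries columns gene, variant, substrate, ssep_score. Observed
    uptake is compared on the model (log10 ratio) scale for RMSE, by rank for
    rho and rank error, per substrate for substrate-level correlations, per
    gene for reduced-function AUC (uptake < 50 positive, score negated), and
    across three activity bins with an increasing-trend test.
    """
    from .model import target_transform

    merged = table.df.merge(scores, on=["gene", "variant", "substrate"], how="inner")
    if len(merged) < 3:
        raise ValueError("need >= 3 matched variant-substrate pairs to evaluate")
    obs = target_transform(merged["uptake_pct_wt"].to_numpy())
    pred = merged["ssep_score"].to_numpy(dtype=float)
    rho, p = spearman(pred, obs)
    per_sub = {}
    for substrate, grp in merged.groupby("substrate"):
        if len(grp) < min_per_substrate:
            continue
        o = target_transform(grp["uptake_pct_wt"].to_numpy())
        s = grp["ssep_score"].to_numpy(dtype=float)
        if np.unique(o).size < 2 or np.unique(s).size < 2:
            continue
        per_sub[substrate], _ = spearman(s, o)
    per_gene_auc = {}
    for gene, grp in merged.groupby("gene"):
        labels = np.array([bin_activity(u, "threshold_50") for u in grp["uptake_pct_wt"]])
        if labels.min() == labels.max() or np.unique(grp["ssep_score"]).size < 2:
            continue
        per_gene_auc[gene] = roc_auc(-grp["ssep_score"].to_numpy(dtype=float), labels)
    bins = {"decreased": [], "neutral": [], "increased": []}
    for u, s in zip(merged["uptake_pct_wt"], pred):
        bins[bin_activity(u)].append(float(s))
    ordered = [bins["decreased"], bins["neutral"], bins["increased"]]
    jt_p = None
    if sum(1 for g in ordered if g) >= 2:
        _, jt_p = jonckheere_test([g for g in ordered if g])
    return EvalReport(
        spearman_rho=rho, spearman_p=p,
        rmse=rmse(pred, obs), rank_errors=rank_error(pred, obs),
        per_substrate_rho=per_sub, per_gene_auc=per_gene_auc,
        jonckheere_p=jt_p, binned_scores=bins,
    )
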