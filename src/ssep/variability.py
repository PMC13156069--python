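"""Substrate-specificity profiling of transporter variants.

For each variant measured against several substrates this module computes the
within-variant activity span (max - min of %WT values), the span ratio
(max/min), the sample SD, and direction flags, then summarizes per transporter
the fraction of variants with high substrate-dependent variability (span >= 50
%WT by default) and with mixed directionality (some substrates above and some
below wildtype).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_data import ActivityTable

__all__ = [
    "VariantSubstrateProfile",
    "TransporterSummary",
    "profile_variant",
    "mixed_direction",
    "top_span_variants",
    "summarize_transporter",
    "log_display",
]

DEFAULT_SPAN_THRESHOLD = 50.0


@dataclass(frozen=True)
class VariantSubstrateProfile:
    variant: str
    n_substrates: int
    values: tuple[float, ...]
    median: float
    sd: float
    span: float
    span_ratio: float  # nan when min == 0
    mixed_direction: bool
    high_variability: bool


@dataclass
class TransporterSummary:
    gene: str
    n_variants_profiled: int
    pct_high_variability: float
    pct_mixed_direction: float
    sd_values: list[float] = field(default_factory=list)
    variants_by_median: list[str] = field(default_factory=list)
    profiles: dict[str, VariantSubstrateProfile] = field(default_factory=dict)


def mixed_direction(values) -> bool:
    """True iff some value is strictly above 100 %WT and some strictly below.

    Values exactly at 100 count as neither direction.
    """
    v = np.asarray(values, dtype=float)
    return bool((v > 100).any() and (v < 100).any())


def profile_variant(
    values,
    variant: str = "",
    span_threshold: float = DEFAULT_SPAN_THRESHOLD,
) -> VariantSubstrateProfile:
    """Profile one variant's %WT values across substrates.

    span = max - min; sd is the sample (n-1) standard deviation (0 for n = 1);
    high_variability iff span >= span_threshold. span_ratio is max/min, NaN
    when the minimum is 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("profile_variant requires at least one value")
    if (v < 0).any():
        raise ValueError("%WT values must be >= 0")
    span = float(v.max() - v.min())
    ratio = float(v.max() / v.min()) if v.min() > 0 else float("nan")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return VariantSubstrateProfile(
        variant=variant,
        n_substrates=int(v.size),
        values=tuple(float(x) for x in v),
        median=float(np.median(v)),
        sd=sd,
        span=span,
        span_ratio=ratio,
        mixed_direction=mixed_direction(v),
        high_variability=span >= span_threshold,
    )


def top_span_variants(profiles, k: int = 3) -> list[str]:
    """The k variants with the highest span ratio (max/min %WT).

    Profiles containing a zero value (undefined ratio) are excluded with a
    warning. Ties break by larger span, then lexicographic label.
    """
    usable = []
    for p in profiles:
        if not np.isfinite(p.span_ratio):
            warnings.warn(
                f"variant {p.variant!r} has a zero %WT value; span ratio undefined, excluded"
            )
            continue
        usable.append(p)
    usable.sort(key=lambda p: (-p.span_ratio, -p.span, p.variant))
    return [p.variant for p in usable[:k]]


def summarize_transporter(
    table: ActivityTable,
    gene: str,
    span_threshold: float = DEFAULT_SPAN_THRESHOLD,
) -> TransporterSummary:
    """Per-transporter substrate-variability summary.

    Only variants with measurements for at least two substrates are profiled.
    Percentages of high-variability and mixed-direction variants are computed
    over that set; variants are ordered by their median uptake ratio.
    """
    sub = table.for_gene(gene)
    profiles: dict[str, VariantSubstrateProfile] = {}
    for variant, grp in sub.groupby("variant"):
        if grp["substrate"].nunique() < 2:
            continue
        profiles[variant] = profile_variant(
            grp["uptake_pct_wt"].to_numpy(), variant=variant, span_threshold=span_threshold
        )
    n = len(profiles)
    if n == 0:
        return TransporterSummary(gene=gene, n_variants_profiled=0,
                                  pct_high_variability=0.0, pct_mixed_direction=0.0)
    n_high = sum(p.high_variability for p in profiles.values())
    n_mixed = sum(p.mixed_direction for p in profiles.values())
    ordered = sorted(profiles.values(), key=lambda p: (p.median, p.variant))
    return TransporterSummary(
        gene=gene,
        n_variants_profiled=n,
        pct_high_variability=100.0 * n_high / n,
        pct_mixed_direction=100.0 * n_mixed / n,
        sd_values=[p.sd for p in ordered],
        variants_by_median=[p.variant for p in ordered],
        profiles=profiles,
    )


def log_display(x):
    """Presentation-only log transform for uptake ratios: log10(1 + x)."""
    return np.log10(1.0 + np.asarray(x, dtype=float))
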