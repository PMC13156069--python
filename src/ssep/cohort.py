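"""Cohort-level association between weighted variant burden and drug dose.

The clinical layer: derive maintenance daily doses from prescription rows,
filter rare variants (MAF < 0.05), build per-subject burden scores as the
dosage-weighted sum over variants (weights are substrate-specific predicted
activities or substrate-agnostic mean activities), and regress dose on
burden with covariate adjustment (age at prescription, sex, ethnic group,
BMI). Gene-level rare-variant tests are a covariate-adjusted burden score
test and a SKAT-style variance-component test, combined into a permutation
min-p omnibus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortVariant",
    "BurdenResult",
    "DamagingThreshold",
    "DEFAULT_DAMAGING_THRESHOLDS",
    "derive_daily_dose",
    "maf_filter",
    "burden_score",
    "fit_dose_model",
    "classify_damaging",
    "burden_test",
    "skat_style_test",
]

DEFAULT_MAF_THRESHOLD = 0.05


@dataclass
class CohortVariant:
    """One rare variant: per-subject allele dosages plus weighting metadata."""

    id: str
    gene: str
    dosages: np.ndarray  # in [0, 2] per subject
    maf: float | None = None
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if not np.all(np.isfinite(self.dosages)):
            raise ValueError(f"variant {self.id}: non-finite dosages")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"variant {self.id}: MAF {self.maf} outside [0, 0.5]")


@dataclass(frozen=True)
class BurdenResult:
    beta: float            # mg/day per unit burden
    ci95: tuple[float, float]
    p: float
    n_subjects: int
    weight_scheme: str = ""
    se: float = float("nan")


def derive_daily_dose(prescriptions: pd.DataFrame,
                      aggregator: str = "median") -> tuple[pd.Series, int]:
    """Derive per-subject maintenance daily doses from prescription rows.

    Expects columns subject_id, strength_mg, quantity, duration_days. Each
    valid row contributes ``strength_mg * quantity / duration_days`` mg/day;
    a subject's maintenance dose is the median (or mean) across their valid
    prescriptions. Rows with missing or non-positive fields are dropped;
    the dropped-row count is returned alongside the doses. Subjects with no
    valid prescription are excluded.
    """
    required = ["subject_id", "strength_mg", "quantity", "duration_days"]
    missing = [c for c in required if c not in prescriptions.columns]
    if missing:
        raise ValueError(f"prescriptions missing columns: {missing}")
    df = prescriptions.copy()
    numeric = ["strength_mg", "quantity", "duration_days"]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    valid = df[numeric].notna().all(axis=1) & (df[numeric] > 0).all(axis=1)
    n_dropped = int((~valid).sum())
    df = df[valid]
    doses = df["strength_mg"] * df["quantity"] / df["duration_days"]
    agg = doses.groupby(df["subject_id"]).median() if aggregator == "median" \
        else doses.groupby(df["subject_id"]).mean()
    agg.name = "daily_dose"
    return agg, n_dropped


def maf_filter(variants: Sequence[CohortVariant],
               threshold: float = DEFAULT_MAF_THRESHOLD) -> list[CohortVariant]:
    """Keep variants with MAF strictly below the threshold.

    Variants without a recorded MAF are excluded with a warning.
    """
    kept = []
    for v in variants:
        if v.maf is None:
            warnings.warn(f"variant {v.id} has no MAF; excluded from the rare set")
            continue
        if v.maf < threshold:
            kept.append(v)
    return kept


def burden_score(variants: Sequence[CohortVariant], scheme: str) -> np.ndarray:
    """Per-subject weighted burden: sum over variants of dosage x weight."""
    if not variants:
        raise ValueError("burden_score requires >= 1 variant")
    n = variants[0].dosages.size
    score = np.zeros(n)
    for v in variants:
        if scheme not in v.weights:
            raise ValueError(f"variant {v.id} has no weight under scheme {scheme!r}")
        if v.dosages.size != n:
            raise ValueError(f"variant {v.id}: dosage length mismatch")
        score += v.dosages * v.weights[scheme]
    return score


def _design_matrix(covariates: pd.DataFrame | None, n: int) -> pd.DataFrame:
    """Intercept + one-hot covariates (reference level dropped)."""
    cols = {"const": np.ones(n)}
    X = pd.DataFrame(cols)
    if covariates is not None and len(covariates.columns):
        if len(covariates) != n:
            raise ValueError("covariate rows do not match subject count")
        dummies = pd.get_dummies(covariates, drop_first=True, dtype=float)
        X = pd.concat([X.reset_index(drop=True), dummies.reset_index(drop=True)], axis=1)
    return X


def fit_dose_model(burden, covariates: pd.DataFrame | None, daily_dose,
                   weight_scheme: str = "") -> BurdenResult:
    """OLS of daily dose on burden with covariate adjustment.

    Categorical covariates are one-hot encoded against a reference level.
    Returns the burden coefficient with its normal-theory 95% CI and
    two-sided p. Rank-deficient designs are an error naming aliased columns.
    """
    import statsmodels.api as sm

    burden = np.asarray(burden, dtype=float)
    y = np.asarray(daily_dose, dtype=float)
    n = y.size
    X = _design_matrix(covariates, n)
    X.insert(1, "burden", burden)
    if n <= X.shape[1]:
        raise ValueError(f"n={n} subjects <= {X.shape[1]} parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns by pivoted QR
        q, r, piv = __import__("scipy").linalg.qr(X.to_numpy(), pivoting=True)
        aliased = [X.columns[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int().loc["burden"]
    return BurdenResult(
        beta=float(fit.params["burden"]),
        ci95=(float(ci[0]), float(ci[1])),
        p=float(fit.pvalues["burden"]),
        n_subjects=int(n),
        weight_scheme=weight_scheme,
        se=float(fit.bse["burden"]),
    )


@dataclass(frozen=True)
class DamagingThreshold:
    """Direction-aware damaging cutoff for one predictor."""

    cutoff: float
    damaging_if: str  # "below" or "above"

    def is_damaging(self, score: float) -> bool:
        return score <= self.cutoff if self.damaging_if == "below" else score >= self.cutoff


# Literature-default damaging thresholds; every entry is overrideable.
# SSEP: lower score = less transport; scores below -0.3 (half of wildtype
# activity on the log10 ratio scale) are treated as damaging.
DEFAULT_DAMAGING_THRESHOLDS: dict[str, DamagingThreshold] = {
    "SSEP": DamagingThreshold(np.log10(0.5), "below"),
    "SIFT": DamagingThreshold(0.05, "below"),
    "SIFT4G": DamagingThreshold(0.05, "below"),
    "PolyPhen2_HDIV": DamagingThreshold(0.957, "above"),
    "PolyPhen2_HVAR": DamagingThreshold(0.909, "above"),
    "CADD": DamagingThreshold(20.0, "above"),
    "REVEL": DamagingThreshold(0.5, "above"),
    "AlphaMissense": DamagingThreshold(0.564, "above"),
    "MetaLR": DamagingThreshold(0.5, "above"),
    "MetaSVM": DamagingThreshold(0.0, "above"),
    "PROVEAN": DamagingThreshold(-2.5, "below"),
    "ESM1b": DamagingThreshold(-7.5, "below"),
    "FATHMM": DamagingThreshold(-1.5, "below"),
}


def classify_damaging(scores: pd.DataFrame,
                      thresholds: Mapping[str, DamagingThreshold] | None = None
                      ) -> dict[str, set[str]]:
    """Per-predictor damaging variant sets from a score table.

    ``scores`` has a ``variant`` column plus one column per predictor.
    Predictors without a configured threshold are skipped with a warning.
    """
    thresholds = dict(DEFAULT_DAMAGING_THRESHOLDS if thresholds is None else thresholds)
    out: dict[str, set[str]] = {}
    predictors = [c for c in scores.columns if c not in ("gene", "variant")]
    for pred in predictors:
        thr = thresholds.get(pred)
        if thr is None:
            warnings.warn(f"no damaging threshold configured for {pred!r}; skipped")
            continue
        col = pd.to_numeric(scores[pred], errors="coerce")
        mask = col.notna() & col.apply(thr.is_damaging)
        out[pred] = set(scores.loc[mask, "variant"])
    return out


def _adjusted_residuals(y: np.ndarray, covariates: pd.DataFrame | None):
    """Residualize the phenotype on the covariate-only design."""
    X = _design_matrix(covariates, y.size).to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (y.size - X.shape[1])
    return resid, sigma2, X


def burden_test(genotypes, phenotype, covariates: pd.DataFrame | None = None) -> float:
    """Covariate-adjusted score test on the unweighted carrier burden.

    ``genotypes`` is an (n_subjects, n_variants) dosage matrix; the burden is
    the row sum. Returns the two-sided p-value; zero carriers give p = 1
    with a warning.
    """
    from scipy import stats

    G = np.atleast_2d(np.asarray(genotypes, dtype=float))
    y = np.asarray(phenotype, dtype=float)
    b = G.sum(axis=1)
    if not np.any(b > 0):
        warnings.warn("no carriers of any variant; burden test is uninformative")
        return 1.0
    resid, sigma2, X = _adjusted_residuals(y, covariates)
    # residualize the burden on the same covariates
    coef, *_ = np.linalg.lstsq(X, b, rcond=None)
    b_adj = b - X @ coef
    denom = float(b_adj @ b_adj)
    if denom == 0.0:
        warnings.warn("burden is collinear with covariates; p = 1")
        return 1.0
    z = float(b_adj @ resid) / np.sqrt(sigma2 * denom)
    return float(2.0 * stats.norm.sf(abs(z)))


def skat_style_test(genotypes, phenotype, covariates: pd.DataFrame | None = None,
                    weights=None, n_perm: int = 1000, seed: int = 0) -> dict:
    """Variance-component (SKAT-style) test with a permutation min-p omnibus.

    The variance-component statistic is Q = sum_v w_v^2 (g_v' r)^2 on
    covariate-adjusted residuals r; the burden branch uses the squared score
    of the weighted burden. Each branch's p-value and their min-p omnibus are
    calibrated by permuting residuals (exchangeability-valid), ``n_perm``
    draws (warning below 100: limited resolution). All-zero weights give
    p = 1.
    """
    G = np.atleast_2d(np.asarray(genotypes, dtype=float))
    y = np.asarray(phenotype, dtype=float)
    n, m = G.shape
    w = np.ones(m) if weights is None else np.asarray(weights, dtype=float)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives limited p-value resolution")
    if np.all(w == 0):
        return {"p_skat": 1.0, "p_burden": 1.0, "p_omnibus": 1.0}
    resid, _, X = _adjusted_residuals(y, covariates)
    # residualize genotypes on covariates so both branches are adjusted
    coef, *_ = np.linalg.lstsq(X, G, rcond=None)
    G_adj = G - X @ coef
    burden = G_adj @ w

    def q_stat(r: np.ndarray) -> float:
        return float(((G_adj.T @ r) ** 2 * w ** 2).sum())

    def b_stat(r: np.ndarray) -> float:
        return float((burden @ r) ** 2)

    q_obs, b_obs = q_stat(resid), b_stat(resid)
    rng = np.random.default_rng(seed)
    q_null = np.empty(n_perm)
    b_null = np.empty(n_perm)
    for i in range(n_perm):
        r = rng.permutation(resid)
        q_null[i] = q_stat(r)
        b_null[i] = b_stat(r)
    p_skat = float((1 + (q_null >= q_obs - 1e-12).sum()) / (1 + n_perm))
    p_burden = float((1 + (b_null >= b_obs - 1e-12).sum()) / (1 + n_perm))
    # min-p omnibus, calibrated against the permutation distribution of min-p
    q_rank = np.argsort(np.argsort(-q_null))
    b_rank = np.argsort(np.argsort(-b_null))
    p_q_null = (1 + q_rank) / n_perm
    p_b_null = (1 + b_rank) / n_perm
    minp_null = np.minimum(p_q_null, p_b_null)
    minp_obs = min(p_skat, p_burden)
    p_omni = float((1 + (minp_null <= minp_obs + 1e-12).sum()) / (1 + n_perm))
    return {"p_skat": p_skat, "p_burden": p_burden, "p_omnibus": p_omni,
            "q_statistic": q_obs, "burden_statistic": b_obs}
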