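"""Domain types and I/O for transporter variant activity data.

Activity is stored throughout as percent of wildtype uptake (100 = wildtype);
sources quoting fold-change ratios are converted (x100) at ingestion. Replicate
measurements for the same (gene, variant, substrate) key are aggregated by the
unweighted arithmetic mean.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantKind",
    "VariantSpec",
    "ActivityRecord",
    "ActivityTable",
    "DMSRecord",
    "VariantParseError",
    "SchemaError",
    "parse_variant",
    "aggregate_measurements",
    "read_activity_table",
    "write_activity_table",
    "normalize_dms",
]


class VariantParseError(ValueError):
    """Raised when a protein-level variant label cannot be parsed."""


class SchemaError(ValueError):
    """Raised when a delimited input file lacks required columns."""


AA1 = set("ACDEFGHIKLMNPQRSTVWY")

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}


class VariantKind(str, Enum):
    MISSENSE = "missense"
    SINGLE_RESIDUE_DELETION = "single_residue_deletion"
    OTHER_INDEL = "other_indel"


@dataclass(frozen=True)
class VariantSpec:
    """A protein-level variant: p.<ref><pos><alt> or p.<ref><pos>del."""

    kind: VariantKind
    position: int
    ref_aa: str | None = None
    alt_aa: str | None = None
    gene: str | None = None
    end_position: int | None = None  # multi-residue deletions only
    end_ref_aa: str | None = None

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.kind is VariantKind.MISSENSE and self.ref_aa == self.alt_aa:
            raise ValueError("missense variant requires ref_aa != alt_aa")

    @property
    def label(self) -> str:
        if self.kind is VariantKind.MISSENSE:
            return f"p.{self.ref_aa}{self.position}{self.alt_aa}"
        if self.kind is VariantKind.SINGLE_RESIDUE_DELETION:
            return f"p.{self.ref_aa}{self.position}del"
        return f"p.{self.ref_aa}{self.position}_{self.end_ref_aa}{self.end_position}del"

    def __str__(self) -> str:
        return self.label


_AA_TOKEN = r"(?:[A-Z][a-z]{2}|[A-Z])"
_MISSENSE_RE = re.compile(rf"^(?:p\.)?({_AA_TOKEN})(\d+)({_AA_TOKEN})$")
_DEL_RE = re.compile(rf"^(?:p\.)?({_AA_TOKEN})(\d+)del$")
_RANGE_DEL_RE = re.compile(rf"^(?:p\.)?({_AA_TOKEN})(\d+)_({_AA_TOKEN})(\d+)del$")


def _one_letter(token: str, label: str) -> str:
    if len(token) == 1:
        if token not in AA1:
            raise VariantParseError(
                f"unknown amino-acid code {token!r} in variant label {label!r}"
            )
        return token
    try:
        return AA3_TO_1[token]
    except KeyError:
        raise VariantParseError(
            f"unknown amino-acid code {token!r} in variant label {label!r}"
        ) from None


def parse_variant(label: str, gene: str | None = None) -> VariantSpec:
    """Parse a protein-variant label into a canonical :class:`VariantSpec`.

    Accepts one-letter or three-letter amino-acid codes, with or without the
    leading ``p.``. Deletion labels (``p.M420del``) map to single-residue
    deletions; range deletions (``p.M420_L423del``) map to ``other_indel``.

    Raises
    ------
    VariantParseError
        If the label is empty or malformed; the message names the offending
        token.
    """
    if not label or not label.strip():
        raise VariantParseError("empty variant label")
    s = label.strip()
    try:
        return _parse_variant_inner(s, gene)
    except VariantParseError:
        raise
    except ValueError as exc:
        raise VariantParseError(f"invalid variant label {s!r}: {exc}") from exc


def _parse_variant_inner(s: str, gene: str | None) -> VariantSpec:
    m = _DEL_RE.match(s)
    if m:
        ref = _one_letter(m.group(1), s)
        return VariantSpec(
            kind=VariantKind.SINGLE_RESIDUE_DELETION,
            position=int(m.group(2)), ref_aa=ref, gene=gene,
        )
    m = _RANGE_DEL_RE.match(s)
    if m:
        ref = _one_letter(m.group(1), s)
        end_ref = _one_letter(m.group(3), s)
        pos, end = int(m.group(2)), int(m.group(4))
        if end <= pos:
            raise VariantParseError(f"deletion range end {end} <= start {pos} in {s!r}")
        return VariantSpec(
            kind=VariantKind.OTHER_INDEL, position=pos, ref_aa=ref,
            end_position=end, end_ref_aa=end_ref, gene=gene,
        )
    m = _MISSENSE_RE.match(s)
    if m:
        ref = _one_letter(m.group(1), s)
        alt = _one_letter(m.group(3), s)
        if ref == alt:
            raise VariantParseError(f"synonymous label {s!r} is not a missense variant")
        return VariantSpec(
            kind=VariantKind.MISSENSE, position=int(m.group(2)),
            ref_aa=ref, alt_aa=alt, gene=gene,
        )
    raise VariantParseError(f"malformed variant label {s!r}")


@dataclass(frozen=True)
class ActivityRecord:
    """One (gene, variant, substrate) uptake measurement, in % of wildtype."""

    gene: str
    variant: str          # canonical label
    substrate: str
    uptake_pct_wt: float
    smiles: str = ""
    source: str = ""

    def __post_init__(self):
        if self.uptake_pct_wt < 0:
            raise ValueError(f"uptake_pct_wt must be >= 0, got {self.uptake_pct_wt}")


REQUIRED_COLUMNS = ["gene", "variant", "substrate", "uptake_pct_wt"]
KEY_COLUMNS = ["gene", "variant", "substrate"]


@dataclass
class ActivityTable:
    """Aggregated activity table: one row per (gene, variant, substrate)."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=REQUIRED_COLUMNS + ["n_replicates"]))

    def __len__(self) -> int:
        return len(self.df)

    def genes(self) -> list[str]:
        return sorted(self.df["gene"].unique()) if len(self.df) else []

    def for_gene(self, gene: str) -> pd.DataFrame:
        return self.df[self.df["gene"] == gene]

    def smiles_for(self, substrate: str) -> str | None:
        if "smiles" not in self.df.columns:
            return None
        rows = self.df.loc[self.df["substrate"] == substrate, "smiles"]
        rows = rows[rows.astype(str).str.len() > 0]
        return None if rows.empty else str(rows.iloc[0])


def aggregate_measurements(records: Iterable[ActivityRecord]) -> ActivityTable:
    """Aggregate replicate measurements by unweighted arithmetic mean per key.

    The replicate count is retained in ``n_replicates``. An empty input yields
    an empty table.
    """
    records = list(records)
    if not records:
        return ActivityTable()
    raw = pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "variant": [parse_variant(r.variant).label for r in records],
            "substrate": [r.substrate for r in records],
            "smiles": [r.smiles for r in records],
            "uptake_pct_wt": [float(r.uptake_pct_wt) for r in records],
            "source": [r.source for r in records],
        }
    )
    agg = (
        raw.groupby(KEY_COLUMNS, as_index=False)
        .agg(
            uptake_pct_wt=("uptake_pct_wt", "mean"),
            n_replicates=("uptake_pct_wt", "size"),
            smiles=("smiles", "first"),
            source=("source", lambda s: ";".join(sorted(set(x for x in s if x)))),
        )
        .sort_values(KEY_COLUMNS, kind="mergesort")
        .reset_index(drop=True)
    )
    return ActivityTable(agg[KEY_COLUMNS + ["uptake_pct_wt", "n_replicates", "smiles", "source"]])


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_activity_table(path: str | Path) -> ActivityTable:
    """Read an activity table from delimited text (TSV default, CSV by extension).

    Required columns: gene, variant, substrate, uptake_pct_wt. Unknown extra
    columns are preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {', '.join(missing)}")
    df["variant"] = [parse_variant(v).label for v in df["variant"]]
    df["uptake_pct_wt"] = df["uptake_pct_wt"].astype(float)
    if "n_replicates" not in df.columns:
        df["n_replicates"] = 1
    df["n_replicates"] = df["n_replicates"].astype(np.int64)
    if "smiles" in df.columns:
        df["smiles"] = df["smiles"].fillna("").astype(str)
    if "source" in df.columns:
        df["source"] = df["source"].fillna("").astype(str)
    if (df["uptake_pct_wt"] < 0).any():
        raise ValueError(f"{path}: negative uptake_pct_wt values")
    df = df.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(drop=True)
    return ActivityTable(df)


def write_activity_table(table: ActivityTable, path: str | Path) -> None:
    """Write a table as delimited text; round-trips losslessly with the reader."""
    path = Path(path)
    df = table.df.copy()
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.10g")


@dataclass(frozen=True)
class DMSRecord:
    """A deep-mutational-scanning score, raw and on the model target scale."""

    gene: str
    variant: str
    raw_score: float
    normalized_score: float


def normalize_dms(
    scores: Sequence[float],
    variants: Sequence[str] | None = None,
    gene: str = "",
    pretrain_targets: Sequence[float] | None = None,
    wt_raw_score: float | None = None,
) -> list[DMSRecord]:
    """Rank-quantile normalize DMS scores onto the model target scale.

    Raw scores are mapped by their mid-ranks ``(rank - 0.5)/n`` onto the
    empirical quantiles of ``pretrain_targets`` (the log10 activity-ratio
    distribution the regressor is trained against). If ``wt_raw_score`` is
    given, the map is shifted so a wildtype-equivalent raw score lands at 0
    (wildtype anchor of the target scale). Without pretraining targets the
    scores are mapped onto standard-normal quantiles scaled to SD 0.3, a
    typical log10-activity spread.

    The mapping is strictly monotone in the raw score.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2 or np.unique(scores).size < 2:
        raise ValueError("normalize_dms requires >= 2 distinct raw scores")
    from scipy.stats import norm, rankdata

    def transform(vals: np.ndarray) -> np.ndarray:
        # mid-rank quantiles of vals within the raw-score distribution
        order = np.searchsorted(np.sort(scores), vals, side="left") + 0.5 * (
            np.searchsorted(np.sort(scores), vals, side="right")
            - np.searchsorted(np.sort(scores), vals, side="left")
        )
        q = np.clip(order / scores.size, 1e-6, 1 - 1e-6)
        if pretrain_targets is not None:
            return np.quantile(np.asarray(pretrain_targets, float), q)
        return norm.ppf(q) * 0.3

    ranks = rankdata(scores, method="average")
    q = np.clip((ranks - 0.5) / scores.size, 1e-6, 1 - 1e-6)
    if pretrain_targets is not None:
        normed = np.quantile(np.asarray(pretrain_targets, float), q)
    else:
        normed = norm.ppf(q) * 0.3
    if wt_raw_score is not None:
        normed = normed - transform(np.array([wt_raw_score]))[0]
    if variants is None:
        variants = [""] * scores.size
    return [
        DMSRecord(gene=gene, variant=v, raw_score=float(s), normalized_score=float(t))
        for v, s, t in zip(variants, scores, normed)
    ]
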