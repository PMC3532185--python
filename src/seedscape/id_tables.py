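"""Replicate identification-table parsing, merging and quantification.

Protein tables arrive as delimited text (comma or tab, auto-detected) with
one row per identified protein per replicate. Merging collapses the
replicates to one row per protein, computes the repeat rate (number of
replicates containing the protein), averages the numeric columns over the
replicates where the protein was seen, and drops proteins below a minimum
repeat rate. Quantification columns: ``ng_avg`` (nanograms from the internal
standard calibration, taken as given) and ``pct_tsp`` (percent of total
soluble protein, ``100 * ng / sum(ng)``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from seedscape.db_assessment import Histogram, value_distribution
from seedscape.rounding import round_half_away

log = logging.getLogger(__name__)

#: Canonical merged-table column order (mirrors the printed report layout).
MERGED_COLUMNS = [
    "uniprot_code", "description", "protein_mw", "score_avg", "products_avg",
    "peptides_avg", "fmol_variation", "ng_avg", "repeat_rate", "pct_tsp",
]

#: Closed vocabulary of peptide match types. Unknown strings are an error.
MATCH_TYPES = (
    "PepFrag1", "PepFrag2", "VarMod", "InSource", "MissedCleavage",
    "NeutralLoss_H2O", "NeutralLoss_NH3",
)

_MANDATORY = ("uniprot_code", "description", "score", "peptides", "ng")

# Header aliases, lowercased with spaces/percent signs normalised away.
_ALIASES: dict[str, str] = {
    "uniprot code": "uniprot_code",
    "uniprot_code": "uniprot_code",
    "accession": "uniprot_code",
    "description": "description",
    "protein mw": "protein_mw",
    "protein_mw": "protein_mw",
    "mw": "protein_mw",
    "scoreavg": "score_avg",
    "score_avg": "score_avg",
    "score": "score",
    "productsavg": "products_avg",
    "products_avg": "products_avg",
    "products": "products",
    "peptidesavg": "peptides_avg",
    "peptides_avg": "peptides_avg",
    "peptides": "peptides",
    "fmol covariance": "fmol_variation",
    "fmol_variation": "fmol_variation",
    "fmol": "fmol",
    "ngramavg": "ng_avg",
    "ng_avg": "ng_avg",
    "ng": "ng",
    "ngram": "ng",
    "repeate rate": "repeat_rate",
    "repeat rate": "repeat_rate",
    "repeat_rate": "repeat_rate",
    "of tsp": "pct_tsp",
    "pct_tsp": "pct_tsp",
}

_NUMERIC_COLUMNS = ("protein_mw", "score_avg", "products_avg", "peptides_avg",
                    "fmol_variation", "ng_avg", "pct_tsp", "score", "products",
                    "peptides", "fmol", "ng")


def _canonical_column(name: str) -> str:
    key = name.strip().lower().replace("%", "").replace(".", " ").strip()
    key = " ".join(key.split())
    return _ALIASES.get(key, name.strip())


def read_protein_table(path: str | Path, merged: bool = False) -> pd.DataFrame:
    """Read one delimited protein table with header auto-mapping.

    ``merged=True`` validates against the merged-table column set (used for
    the packaged reference table); otherwise per-replicate column names
    (score, peptides, ng, ...) are expected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    df.columns = [_canonical_column(c) for c in df.columns]
    required = (
        ("uniprot_code", "description", "score_avg", "peptides_avg", "ng_avg")
        if merged
        else _MANDATORY
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    if df.empty:
        log.warning("%s: header-only table, no rows", path)
    for col in df.columns:
        if col in _NUMERIC_COLUMNS:
            df[col] = _to_numeric(df[col], path, col)
    if "repeat_rate" in df.columns:
        df["repeat_rate"] = _to_numeric(df["repeat_rate"], path, "repeat_rate").astype("Int64")
    return df


def _to_numeric(series: pd.Series, path: Path, col: str) -> pd.Series:
    # blank cells mean absent-not-zero
    blank = series.astype(str).str.strip() == ""
    converted = pd.to_numeric(series.where(~blank, other=None), errors="coerce")
    bad = (~blank) & converted.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ValueError(
            f"{path}: non-numeric value {series[bad].iloc[0]!r} "
            f"in column {col!r} at line {row}"
        )
    return converted


@dataclass
class ReplicateSet:
    """Per-replicate protein tables (and optionally peptide tables), keyed by
    replicate id 1..R."""

    protein_tables: dict[int, pd.DataFrame]
    peptide_tables: dict[int, pd.DataFrame] | None = None

    def __post_init__(self) -> None:
        if not self.protein_tables:
            raise ValueError("at least one replicate table required")

    @property
    def n_replicates(self) -> int:
        return len(self.protein_tables)

    @classmethod
    def from_paths(cls, paths: Sequence[str | Path]) -> "ReplicateSet":
        tables = {i + 1: read_protein_table(p) for i, p in enumerate(paths)}
        return cls(protein_tables=tables)


@dataclass
class MergedTable:
    """Merged identification result plus merge provenance."""

    df: pd.DataFrame
    n_replicates: int
    min_repeat: int

    def __len__(self) -> int:
        return len(self.df)


def merge_replicates(reps: ReplicateSet, min_repeat: int = 2) -> MergedTable:
    """Collapse replicate tables to one row per protein.

    Per protein: ``repeat_rate`` is the number of replicates containing it;
    numeric fields are averaged over the replicates where present;
    ``fmol_variation`` is sd/mean (coefficient of variation) of the
    per-replicate fmol values, blank with fewer than two observations. Rows
    with ``repeat_rate < min_repeat`` are dropped; output is sorted by
    ``ng_avg`` descending, then accession.
    """
    R = reps.n_replicates
    if not 1 <= min_repeat <= R:
        raise ValueError(f"min_repeat must be in [1, {R}], got {min_repeat}")

    frames = []
    for rep_id, table in reps.protein_tables.items():
        if table.empty:
            continue
        t = table.copy()
        t["replicate_id"] = rep_id
        frames.append(t)
    if not frames:
        raise ValueError("all replicate tables are empty")
    stacked = pd.concat(frames, ignore_index=True)

    rows = []
    for code, group in stacked.groupby("uniprot_code", sort=False):
        rate = group["replicate_id"].nunique()
        fmol = group["fmol"].dropna() if "fmol" in group else pd.Series(dtype=float)
        if len(fmol) >= 2 and fmol.mean() != 0:
            cv = float(fmol.std(ddof=1) / fmol.mean())
        else:
            cv = math.nan
        rows.append(
            {
                "uniprot_code": code,
                "description": group["description"].iloc[0],
                "protein_mw": group["protein_mw"].mean() if "protein_mw" in group else math.nan,
                "score_avg": group["score"].mean(),
                "products_avg": group["products"].mean() if "products" in group else math.nan,
                "peptides_avg": group["peptides"].mean(),
                "fmol_variation": cv,
                "ng_avg": group["ng"].mean(),
                "repeat_rate": rate,
            }
        )
    merged = pd.DataFrame(rows)
    merged = merged[merged["repeat_rate"] >= min_repeat]
    merged = merged.sort_values(
        ["ng_avg", "uniprot_code"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    merged["pct_tsp"] = math.nan
    return MergedTable(df=merged[MERGED_COLUMNS], n_replicates=R, min_repeat=min_repeat)


def apply_min_repeat(df: pd.DataFrame, min_repeat: int) -> pd.DataFrame:
    """Filter an already-merged table by minimum repeat rate."""
    return df[df["repeat_rate"] >= min_repeat].reset_index(drop=True)


def percent_tsp(df: pd.DataFrame) -> pd.DataFrame:
    """Recompute ``pct_tsp`` as ``100 * ng_avg / sum(ng_avg)``.

    Rows with absent ng are excluded from numerator and denominator and keep a
    blank share. ``pct_tsp_exact`` holds full precision (sums to exactly 100
    up to float arithmetic); ``pct_tsp`` is rounded to two decimals.
    """
    ng = df["ng_avg"]
    total = ng.sum(skipna=True)
    if not total > 0:
        raise ValueError("no ng values to normalise: total soluble protein is 0")
    out = df.copy()
    exact = 100.0 * ng / total
    out["pct_tsp_exact"] = exact
    out["pct_tsp"] = exact.map(lambda x: round_half_away(x, 2) if pd.notna(x) else x)
    return out


def repeat_rate_summary(df: pd.DataFrame) -> tuple[dict[int, int], dict[int, int]]:
    """Counts and integer-percent fractions of rows at each repeat rate."""
    if df.empty:
        raise ValueError("empty table")
    counts = df["repeat_rate"].value_counts().sort_index()
    n = len(df)
    percents = {int(r): int(round_half_away(100.0 * c / n)) for r, c in counts.items()}
    return {int(r): int(c) for r, c in counts.items()}, percents


def dynamic_range_logs(df: pd.DataFrame) -> tuple[int, float]:
    """Complete decades spanned by the quantification column.

    Returns ``(floor(log10(max/min_positive)), raw ratio)``; zero-ng rows are
    excluded from the minimum.
    """
    ng = df["ng_avg"].dropna()
    positive = ng[ng > 0]
    if positive.empty:
        raise ValueError("no positive ng values")
    ratio = float(positive.max() / positive.min())
    return int(math.floor(math.log10(ratio))), ratio


def keyword_tsp_share(df: pd.DataFrame, pattern: str) -> tuple[int, pd.DataFrame]:
    """Summed ``pct_tsp`` over rows whose description contains ``pattern``
    (case-insensitive substring), rounded to integer percent; also returns the
    matched rows."""
    if "pct_tsp" not in df.columns:
        raise ValueError("pct_tsp not computed; call percent_tsp first")
    mask = df["description"].str.contains(pattern, case=False, regex=False)
    matched = df[mask]
    share = int(round_half_away(matched["pct_tsp"].sum(skipna=True)))
    return share, matched


#: Keyword -> functional category, first match wins. A documented
#: approximation: the original assignment ruleset was never published.
DEFAULT_CATEGORY_RULES: tuple[tuple[str, str], ...] = (
    ("glycinin", "storage"),
    ("conglycinin", "storage"),
    ("albumin", "storage"),
    ("napin", "storage"),
    ("globulin", "storage"),
    ("sucrose binding", "storage"),
    ("lectin", "storage"),
    ("7s storage", "storage"),
    ("inhibitor", "defense/inhibitor"),
    ("amylase", "energy"),
    ("lipoxygenase", "energy"),
    ("ribulose", "energy"),
    ("phosphorylase", "energy"),
    ("chalcone", "energy"),
    ("dehydrin", "abiotic stress"),
    ("lea", "abiotic stress"),
    ("em protein", "abiotic stress"),
    ("embryo", "embryogenesis/maturation"),
    ("maturation", "embryogenesis/maturation"),
    ("uncharacterized", "uncharacterized/other"),
)


@dataclass
class CategorySummary:
    assignments: pd.Series
    share_by_rows: dict[str, float]
    share_by_tsp: dict[str, float] = field(default_factory=dict)


def classify_function(
    df: pd.DataFrame,
    ruleset: Sequence[tuple[str, str]] = DEFAULT_CATEGORY_RULES,
    default_category: str = "uncharacterized/other",
) -> CategorySummary:
    """Assign each row a functional category by first-matching keyword.

    Shares are reported both by row count and (when ``pct_tsp`` is present)
    by summed %TSP, as integer percents.
    """
    if not ruleset:
        raise ValueError("ruleset must be non-empty")
    def assign(description: str) -> str:
        low = description.lower()
        for keyword, category in ruleset:
            if keyword.lower() in low:
                return category
        return default_category

    assignments = df["description"].map(assign)
    n = len(df)
    share_rows = {
        cat: round_half_away(100.0 * cnt / n)
        for cat, cnt in assignments.value_counts().items()
    }
    share_tsp: dict[str, float] = {}
    if "pct_tsp" in df.columns:
        share_tsp = {
            cat: round_half_away(float(df.loc[assignments == cat, "pct_tsp"].sum(skipna=True)))
            for cat in assignments.unique()
        }
    return CategorySummary(assignments=assignments, share_by_rows=share_rows,
                           share_by_tsp=share_tsp)


def _validate_match_types(hits: pd.DataFrame) -> None:
    unknown = set(hits["match_type"]) - set(MATCH_TYPES)
    if unknown:
        raise ValueError(f"unknown match type(s): {sorted(unknown)}")


def match_type_summary(hits: pd.DataFrame) -> dict[str, float]:
    """Fraction of peptide hits per match type, integer percents over the
    closed vocabulary (absent types report 0)."""
    if hits.empty:
        raise ValueError("empty hit set")
    _validate_match_types(hits)
    n = len(hits)
    counts = hits["match_type"].value_counts()
    return {
        mt: round_half_away(100.0 * counts.get(mt, 0) / n) for mt in MATCH_TYPES
    }


def ppm_fraction_within(hits: pd.DataFrame, threshold: float = 5.0) -> float:
    """Fraction (0..1) of hits with ``|ppm_error|`` strictly below the threshold."""
    if hits.empty:
        raise ValueError("empty hit set")
    return float((hits["ppm_error"].abs() < threshold).mean())


def per_protein_distributions(
    hits: pd.DataFrame,
    coverage: Mapping[str, float] | None = None,
    peptide_bins: Sequence[float] = (0, 5, 10, 15, 20, 30, 40, 60, 100, 1000),
    coverage_bins: Sequence[float] = tuple(range(0, 101, 10)),
) -> dict[str, Histogram]:
    """Histograms of matched peptides per protein and optionally of %
    sequence coverage per protein."""
    if hits.empty:
        raise ValueError("empty hit set")
    per_protein = hits.groupby("parent_code").size()
    out = {"peptides_per_protein": value_distribution(per_protein, peptide_bins)}
    if coverage is not None:
        out["coverage"] = value_distribution(list(coverage.values()), coverage_bins)
    return out


def write_merged_table(table: MergedTable | pd.DataFrame, path: str | Path) -> None:
    df = table.df if isinstance(table, MergedTable) else table
    cols = [c for c in MERGED_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)
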