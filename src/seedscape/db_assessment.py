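"""Detectability and distribution statistics over a digested protein database.

A :class:`DetectionWindow` is a peptide-mass interval (open on both sides by
default, so ``(500, 1000)`` means ``500 < m < 1000``). The window scan counts,
for each window and each threshold ``k``, the proteins with at most ``k``
peptide occurrences whose mass falls inside the window. Peptides with an
undefined mass never count as detectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from seedscape.rounding import round_half_away


@dataclass(frozen=True)
class DetectionWindow:
    lower: float
    upper: float = math.inf
    lower_open: bool = True
    upper_open: bool = True

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"window bounds out of order: {self.lower} >= {self.upper}")

    def contains(self, mass: float) -> bool:
        if math.isnan(mass):
            return False
        above = mass > self.lower if self.lower_open else mass >= self.lower
        below = mass < self.upper if self.upper_open else mass <= self.upper
        return above and below

    @property
    def label(self) -> str:
        lo = _fmt(self.lower)
        if math.isinf(self.upper):
            return f">{lo}" if self.lower_open else f">={lo}"
        lo_op = "<" if self.lower_open else "<="
        hi_op = "<" if self.upper_open else "<="
        return f"{lo}{lo_op}x{hi_op}{_fmt(self.upper)}"

    @classmethod
    def parse(cls, text: str) -> "DetectionWindow":
        """Parse ``"500:1000"`` or ``"6000:"`` (open upper end) into a window."""
        lo, _, hi = text.partition(":")
        upper = float(hi) if hi else math.inf
        return cls(lower=float(lo), upper=upper)


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


#: The eleven mass windows used for the detectability tables.
STANDARD_WINDOWS: tuple[DetectionWindow, ...] = tuple(
    DetectionWindow(lo, hi)
    for lo, hi in [
        (500, 1000), (500, 2000), (500, 3000), (500, 4000), (500, 5000),
        (1000, 2000), (2000, 3000), (3000, 4000), (4000, 5000), (5000, 6000),
        (6000, math.inf),
    ]
)


def peptide_window_filter(peptides: pd.DataFrame, window: DetectionWindow) -> pd.DataFrame:
    """Subset of the peptide table whose ``mono_mass`` lies in the window.

    Rows with undefined (NaN) mass are excluded; their count is available as
    ``len(peptides) - len(result) - (# defined-mass rows outside the window)``
    or directly via ``peptides["mono_mass"].isna().sum()``.
    """
    masses = peptides["mono_mass"].to_numpy(dtype=float)
    keep = np.array([window.contains(m) for m in masses], dtype=bool)
    return peptides.loc[keep]


def _window_counts(
    peptides: pd.DataFrame, accessions: Sequence[str], window: DetectionWindow
) -> pd.Series:
    """Per-protein count of window-passing peptide occurrences (0 for proteins
    with no passing peptide)."""
    passing = peptide_window_filter(peptides, window)
    counts = passing.groupby("accession").size()
    return counts.reindex(accessions, fill_value=0)


def proteins_below_peptide_threshold(
    peptides: pd.DataFrame,
    accessions: Sequence[str],
    window: DetectionWindow,
    k: int,
) -> list[str]:
    """Accessions (sorted) of proteins with at most ``k`` peptides in the window.

    ``accessions`` must list every protein in the database, because proteins
    with zero passing peptides are exactly the interesting ones.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    counts = _window_counts(peptides, accessions, window)
    return sorted(counts.index[counts <= k])


@dataclass
class WindowScanResult:
    """Counts (window x k) of proteins with at most k detectable peptides,
    plus the accession list behind every cell."""

    counts: pd.DataFrame  # index: window label, columns: k
    members: Mapping[tuple[str, int], list[str]]
    n_proteins: int

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("window").to_csv(path, sep="\t")


def window_scan(
    peptides: pd.DataFrame,
    accessions: Sequence[str],
    windows: Iterable[DetectionWindow] = STANDARD_WINDOWS,
    ks: Sequence[int] = (0,),
) -> WindowScanResult:
    windows = list(windows)
    if not windows:
        raise ValueError("windows must be non-empty")
    members: dict[tuple[str, int], list[str]] = {}
    data = {}
    for window in windows:
        counts = _window_counts(peptides, accessions, window)
        row = {}
        for k in ks:
            accs = sorted(counts.index[counts <= k])
            members[(window.label, k)] = accs
            row[k] = len(accs)
        data[window.label] = row
    counts_df = pd.DataFrame.from_dict(data, orient="index")[list(ks)]
    return WindowScanResult(counts=counts_df, members=members,
                            n_proteins=len(accessions))


@dataclass
class Histogram:
    """Binned distribution with per-bin fractions of the included items."""

    bin_edges: np.ndarray
    counts: np.ndarray
    fractions: np.ndarray
    n_included: int
    n_excluded: int = 0
    cumulative_below: dict[float, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lower": self.bin_edges[:-1],
                "bin_upper": self.bin_edges[1:],
                "count": self.counts,
                "fraction": self.fractions,
            }
        )


def value_distribution(
    values: Iterable[float],
    bin_edges: Sequence[float],
    thresholds: Sequence[float] = (),
) -> Histogram:
    """Histogram over explicit edges plus cumulative fraction below thresholds.

    ``None``/NaN values are excluded and counted in ``n_excluded``. Works for
    pI values (pH units) and masses (Da) alike.
    """
    arr = np.asarray([v if v is not None else np.nan for v in values], dtype=float)
    defined = arr[~np.isnan(arr)]
    counts, edges = np.histogram(defined, bins=np.asarray(bin_edges, dtype=float))
    n = len(defined)
    fractions = counts / n if n else np.zeros_like(counts, dtype=float)
    cumulative = {t: float((defined < t).sum()) / n if n else math.nan
                  for t in thresholds}
    return Histogram(
        bin_edges=edges,
        counts=counts,
        fractions=fractions,
        n_included=n,
        n_excluded=int(np.isnan(arr).sum()),
        cumulative_below=cumulative,
    )


def pi_distribution(
    values: Iterable[float],
    bin_edges: Sequence[float] = tuple(np.arange(2.0, 14.5, 0.5)),
    thresholds: Sequence[float] = (),
) -> Histogram:
    """pI histogram; default half-pH-unit bins over the realistic range."""
    return value_distribution(values, bin_edges, thresholds)


def database_fractions(numerator_count: int, denominator_count: int) -> float:
    """``100 * numerator / denominator`` as a percent, two decimals,
    half-away-from-zero."""
    if denominator_count <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator_count <= denominator_count:
        raise ValueError("numerator must be within [0, denominator]")
    return round_half_away(100.0 * numerator_count / denominator_count, 2)
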