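"""In-silico protease digestion with missed-cleavage enumeration.

The default rule is trypsin with the Keil suppression: cleave C-terminal to
K/R unless the next residue is proline. Peptide coordinates are 0-based,
half-open ``[start, end)``. The initiator methionine is left in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from seedscape.fasta_io import ProteinDatabase, ProteinRecord
from seedscape.physchem import MassModel, PKSet, isoelectric_point, mono_mass


@dataclass(frozen=True)
class CleavageRule:
    """Positional cleavage rule: cut after ``cut_after`` unless followed by
    a ``suppress_before`` residue (when suppression is enabled)."""

    name: str = "trypsin"
    cut_after: frozenset[str] = frozenset("KR")
    suppress_before: frozenset[str] = frozenset("P")
    apply_suppression: bool = True

    def __post_init__(self) -> None:
        if not self.cut_after:
            raise ValueError("cut_after must be non-empty")

    def without_suppression(self) -> "CleavageRule":
        return replace(self, apply_suppression=False, name=self.name + "/p")


TRYPSIN = CleavageRule()

_RULES: dict[str, CleavageRule] = {
    "trypsin": TRYPSIN,
    "trypsin/p": TRYPSIN.without_suppression(),
    "lys-c": CleavageRule(name="lys-c", cut_after=frozenset("K")),
    "arg-c": CleavageRule(name="arg-c", cut_after=frozenset("R")),
    "glu-c": CleavageRule(name="glu-c", cut_after=frozenset("E")),
}


def get_rule(name: str) -> CleavageRule:
    try:
        return _RULES[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown enzyme {name!r}; known: {sorted(_RULES)}"
        ) from None


@dataclass
class Peptide:
    """A digestion product with parent coordinates and optional mass/pI."""

    parent_accession: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    mono_mass: float | None = None
    pi: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty peptide span [{self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length does not match [start, end) span")

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_sites(sequence: str, rule: CleavageRule = TRYPSIN) -> list[int]:
    """Internal cut positions: site ``i`` means a cut between ``sequence[i-1]``
    and ``sequence[i]``, so ``0 < i < len(sequence)`` always."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    sites = []
    for i in range(1, len(sequence)):
        if sequence[i - 1] not in rule.cut_after:
            continue
        if rule.apply_suppression and sequence[i] in rule.suppress_before:
            continue
        sites.append(i)
    return sites


def digest_protein(
    record: ProteinRecord | str,
    rule: CleavageRule = TRYPSIN,
    max_missed: int = 0,
    accession: str = "",
) -> list[Peptide]:
    """All peptides bounded by termini/cleavage sites spanning at most
    ``max_missed`` internal sites, ordered by (start, end)."""
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if isinstance(record, ProteinRecord):
        sequence, accession = record.sequence, record.accession
    else:
        sequence = record
    if not sequence:
        raise ValueError("cannot digest an empty sequence")

    boundaries = [0] + cleavage_sites(sequence, rule) + [len(sequence)]
    peptides = []
    for i in range(len(boundaries) - 1):
        for missed in range(max_missed + 1):
            j = i + 1 + missed
            if j >= len(boundaries):
                break
            start, end = boundaries[i], boundaries[j]
            peptides.append(
                Peptide(
                    parent_accession=accession,
                    start=start,
                    end=end,
                    sequence=sequence[start:end],
                    missed_cleavages=missed,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


@dataclass
class DigestSummary:
    """Occurrence-level counts from a database digestion."""

    n_proteins: int
    n_peptides_total: int
    n_peptides_fully_cleaved: int
    n_peptides_per_missed_level: dict[int, int] = field(default_factory=dict)
    n_unique_sequences: int = 0
    n_undefined_mass: int = 0

    def as_dict(self) -> dict:
        return {
            "n_proteins": self.n_proteins,
            "n_peptides_total": self.n_peptides_total,
            "n_peptides_fully_cleaved": self.n_peptides_fully_cleaved,
            "n_peptides_per_missed_level": dict(self.n_peptides_per_missed_level),
            "n_unique_sequences": self.n_unique_sequences,
            "n_undefined_mass": self.n_undefined_mass,
        }


PEPTIDE_COLUMNS = ["accession", "start", "end", "sequence", "missed_cleavages",
                   "mono_mass", "pi"]


def digest_database(
    db: ProteinDatabase | Iterable[ProteinRecord],
    rule: CleavageRule = TRYPSIN,
    max_missed: int = 1,
    mass_model: MassModel | None = None,
    pkset: PKSet | None = None,
    compute_mass: bool = True,
    compute_pi: bool = False,
) -> tuple[pd.DataFrame, DigestSummary]:
    """Digest every record; return the peptide table and occurrence counts.

    Counts are over peptide occurrences (a peptide shared by two proteins
    counts twice); a unique-sequence tally is reported alongside. pI
    computation is off by default because it dominates runtime on large
    databases.
    """
    records = list(db)
    if not records:
        raise ValueError("database is empty")

    rows: list[tuple] = []
    per_level: dict[int, int] = {m: 0 for m in range(max_missed + 1)}
    mass_cache: dict[str, float | None] = {}
    pi_cache: dict[str, float | None] = {}
    for record in records:
        for pep in digest_protein(record, rule, max_missed):
            mass = pi = None
            if compute_mass:
                if pep.sequence not in mass_cache:
                    mass_cache[pep.sequence] = mono_mass(pep.sequence, mass_model)
                mass = mass_cache[pep.sequence]
            if compute_pi:
                if pep.sequence not in pi_cache:
                    pi_cache[pep.sequence] = isoelectric_point(pep.sequence, pkset)
                pi = pi_cache[pep.sequence]
            per_level[pep.missed_cleavages] += 1
            rows.append((pep.parent_accession, pep.start, pep.end, pep.sequence,
                         pep.missed_cleavages, mass, pi))

    table = pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)
    summary = DigestSummary(
        n_proteins=len(records),
        n_peptides_total=len(table),
        n_peptides_fully_cleaved=per_level.get(0, 0),
        n_peptides_per_missed_level=per_level,
        n_unique_sequences=table["sequence"].nunique(),
        n_undefined_mass=int(table["mono_mass"].isna().sum()) if compute_mass else 0,
    )
    return table, summary


def brute_force_digest(
    sequence: str, rule: CleavageRule = TRYPSIN, max_missed: int = 0
) -> list[tuple[int, int, int]]:
    """Independent oracle: enumerate every substring and keep those whose
    boundaries are termini or cleavage sites and whose spanned internal site
    count is at most ``max_missed``. Returns (start, end, missed) triples.

    Quadratic; intended for short test sequences only.
    """
    sites = set(cleavage_sites(sequence, rule))
    valid_boundaries = sites | {0, len(sequence)}
    out = []
    for start in range(len(sequence)):
        for end in range(start + 1, len(sequence) + 1):
            if start not in valid_boundaries or end not in valid_boundaries:
                continue
            spanned = sum(1 for s in sites if start < s < end)
            if spanned <= max_missed:
                out.append((start, end, spanned))
    return sorted(out)
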