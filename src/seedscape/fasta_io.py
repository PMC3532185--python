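"""FASTA protein-database I/O with UniProt-style header parsing.

Two header dialects are supported: the UniProt form
``>sp|ACCESSION|ENTRY_NAME Description OS=... GN=... PE=... SV=...`` and the
bare form ``>ACCESSION Description``. All metadata fields are optional;
parsing is best-effort and falls back to the first whitespace-delimited token
as the accession.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

#: Residues outside the 20 canonical amino acids that are tolerated in input.
AMBIGUOUS_RESIDUES = frozenset("BJOUXZ")
_VALID_SEQ = re.compile(r"^[A-Z]+$")

_TAG = re.compile(r"\b(OS|GN|PE|SV)=")


class MalformedHeaderError(ValueError):
    pass


class DuplicateAccessionError(ValueError):
    pass


@dataclass
class ProteinRecord:
    """One database entry: accession, optional metadata and the sequence."""

    accession: str
    sequence: str
    description: str = ""
    entry_name: str = ""
    organism: str = ""
    gene: str = ""
    pe_level: int | None = None
    sv: int | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.accession}: sequence must be non-empty")
        if not _VALID_SEQ.match(self.sequence):
            raise ValueError(
                f"record {self.accession}: sequence contains characters outside A-Z"
            )

    @property
    def ambiguous_residues(self) -> set[str]:
        """Residues present in the sequence that have no defined mass/pK."""
        return set(self.sequence) & AMBIGUOUS_RESIDUES

    @property
    def is_ambiguous(self) -> bool:
        return bool(self.ambiguous_residues)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinDatabase:
    """Ordered collection of :class:`ProteinRecord` with unique accessions."""

    records: list[ProteinRecord] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for record in self.records:
            if record.accession in seen:
                raise DuplicateAccessionError(
                    f"duplicate accession {record.accession!r}"
                )
            seen.add(record.accession)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, accession: str) -> ProteinRecord:
        for record in self.records:
            if record.accession == accession:
                return record
        raise KeyError(accession)

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]


class HeaderFields(NamedTuple):
    accession: str
    entry_name: str
    description: str
    organism: str
    gene: str
    pe_level: int | None
    sv: int | None


def parse_uniprot_header(header_line: str) -> HeaderFields:
    """Extract accession and optional metadata from a FASTA header line.

    Absent fields come back empty (``""``/``None``); unparseable headers fall
    back to the first whitespace token as accession.
    """
    if not header_line or not header_line.startswith(">"):
        raise MalformedHeaderError(f"malformed FASTA header: {header_line!r}")
    body = header_line[1:].strip()
    if not body:
        raise MalformedHeaderError("malformed FASTA header: empty")

    token, _, rest = body.partition(" ")
    entry_name = ""
    pieces = token.split("|")
    if len(pieces) == 3 and pieces[0] in {"sp", "tr"}:
        accession, entry_name = pieces[1], pieces[2]
    else:
        accession = token

    organism = gene = ""
    pe_level = sv = None
    description = rest.strip()
    match = _TAG.search(description)
    if match:
        tail = description[match.start():]
        description = description[: match.start()].strip()
        tags = dict(
            (m.group(1), _tag_value(tail, m))
            for m in _TAG.finditer(tail)
        )
        organism = tags.get("OS", "")
        gene = tags.get("GN", "")
        pe_level = _opt_int(tags.get("PE"))
        sv = _opt_int(tags.get("SV"))
    return HeaderFields(accession, entry_name, description, organism, gene, pe_level, sv)


def _tag_value(tail: str, match: re.Match) -> str:
    nxt = _TAG.search(tail, match.end())
    end = nxt.start() if nxt else len(tail)
    return tail[match.end(): end].strip()


def _opt_int(value: str | None) -> int | None:
    if not value:
        return None
    try:
        return int(value)
    except ValueError:
        return None


def _record_from_seqio(raw_header: str, raw_seq: str, allow_stop: bool = True) -> ProteinRecord:
    fields = parse_uniprot_header(">" + raw_header)
    sequence = "".join(raw_seq.split()).upper()
    if "*" in sequence:
        log.warning("record %s: stripping %d stop character(s)", fields.accession,
                    sequence.count("*"))
        sequence = sequence.replace("*", "")
    if not _VALID_SEQ.match(sequence):
        bad = sorted(set(sequence) - set("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
        raise ValueError(
            f"record {fields.accession}: invalid sequence characters {bad}"
        )
    record = ProteinRecord(
        accession=fields.accession,
        sequence=sequence,
        description=fields.description,
        entry_name=fields.entry_name,
        organism=fields.organism,
        gene=fields.gene,
        pe_level=fields.pe_level,
        sv=fields.sv,
    )
    if record.is_ambiguous:
        log.debug("record %s contains ambiguous residues %s", record.accession,
                  sorted(record.ambiguous_residues))
    return record


def read_fasta(path: str | Path, allow_duplicate_ids: bool = False) -> ProteinDatabase:
    """Read a FASTA protein database.

    Sequences are whitespace-stripped and uppercased; ``*`` is removed with a
    warning. Duplicate accessions are an error unless ``allow_duplicate_ids``
    is set, in which case later copies are suffixed ``__dupN`` and logged.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    with path.open() as handle:
        for seq_record in SeqIO.parse(handle, "fasta"):
            record = _record_from_seqio(seq_record.description, str(seq_record.seq))
            if record.accession in seen:
                if not allow_duplicate_ids:
                    raise DuplicateAccessionError(
                        f"duplicate accession {record.accession!r} in {path}"
                    )
                seen[record.accession] += 1
                relabelled = f"{record.accession}__dup{seen[record.accession]}"
                log.warning("duplicate accession %s relabelled %s",
                            record.accession, relabelled)
                record.accession = relabelled
            seen.setdefault(record.accession, 0)
            records.append(record)
    log.info("read %d records from %s", len(records), path)
    return ProteinDatabase(records=records, source_label=str(path))


def write_fasta(db: ProteinDatabase | Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA, sequences wrapped at ``width`` columns."""
    path = Path(path)
    records = db.records if isinstance(db, ProteinDatabase) else list(db)
    with path.open("w") as handle:
        for record in records:
            handle.write(">" + _format_header(record) + "\n")
            for i in range(0, len(record.sequence), width):
                handle.write(record.sequence[i: i + width] + "\n")


def _format_header(record: ProteinRecord) -> str:
    head = record.accession
    if record.entry_name:
        head = f"sp|{record.accession}|{record.entry_name}"
    parts = [head]
    if record.description:
        parts.append(record.description)
    if record.organism:
        parts.append(f"OS={record.organism}")
    if record.gene:
        parts.append(f"GN={record.gene}")
    if record.pe_level is not None:
        parts.append(f"PE={record.pe_level}")
    if record.sv is not None:
        parts.append(f"SV={record.sv}")
    return " ".join(parts)


def find_duplicate_sequences(db: ProteinDatabase) -> list[list[str]]:
    """Group accessions sharing an identical full sequence (groups of size >= 2).

    Groups are ordered by first appearance; members keep database order.
    """
    by_sequence: dict[str, list[str]] = {}
    for record in db:
        by_sequence.setdefault(record.sequence, []).append(record.accession)
    return [accs for accs in by_sequence.values() if len(accs) >= 2]


def duplicate_report(db: ProteinDatabase) -> pd.DataFrame:
    """Duplicate groups as a table: group_id, accession, sequence_length."""
    rows = []
    for group_id, accessions in enumerate(find_duplicate_sequences(db), start=1):
        for accession in accessions:
            rows.append(
                {
                    "group_id": group_id,
                    "accession": accession,
                    "sequence_length": len(db[accession]),
                }
            )
    return pd.DataFrame(rows, columns=["group_id", "accession", "sequence_length"])
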