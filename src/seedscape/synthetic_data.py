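"""Ground-truth data generators and the packaged reference identification table.

Every generator takes an explicit seed and returns a manifest describing the
planted structure (duplicate groups, fragment parents, true abundances,
per-replicate detections, per-peptide match types and ppm errors), so any
statistic the pipeline computes downstream can be checked against a known
answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from seedscape.digestion import TRYPSIN, digest_protein
from seedscape.fasta_io import ProteinDatabase, ProteinRecord
from seedscape.id_tables import MATCH_TYPES, MergedTable, ReplicateSet, read_protein_table

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Residue frequencies loosely resembling a seed-storage-protein-rich database:
#: enriched in E/Q/N/K/R relative to uniform.
SEED_STORAGE_COMPOSITION: dict[str, float] = {
    "A": 0.055, "C": 0.012, "D": 0.055, "E": 0.095, "F": 0.045, "G": 0.060,
    "H": 0.022, "I": 0.050, "K": 0.065, "L": 0.080, "M": 0.012, "N": 0.065,
    "P": 0.050, "Q": 0.075, "R": 0.060, "S": 0.060, "T": 0.040, "V": 0.055,
    "W": 0.009, "Y": 0.035,
}


@dataclass
class SyntheticDbParams:
    n_proteins: int = 100
    length_log_mean: float = 5.3      # exp(5.3) ~ 200 residues
    length_log_sigma: float = 0.6
    length_min: int = 50
    length_max: int = 800
    composition: dict[str, float] | None = None  # None = uniform
    duplicate_fraction: float = 0.0
    fragment_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        for name in ("duplicate_fraction", "fragment_fraction"):
            frac = getattr(self, name)
            if not 0.0 <= frac < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {frac}")
        if self.duplicate_fraction + self.fragment_fraction >= 1.0:
            raise ValueError("duplicate + fragment fractions must leave room for originals")


def _random_sequence(rng: np.random.Generator, length: int,
                     probs: np.ndarray | None) -> str:
    return "".join(rng.choice(_RESIDUES, size=length, p=probs))


def generate_database(params: SyntheticDbParams) -> tuple[ProteinDatabase, dict]:
    """Generate a synthetic protein database with planted duplicates/fragments.

    The manifest records ``duplicate_groups`` (lists of accessions sharing a
    sequence, including the original) and ``fragment_parents``
    (fragment accession -> parent accession).
    """
    rng = np.random.default_rng(params.seed)
    probs = None
    if params.composition is not None:
        probs = np.array([params.composition[r] for r in _RESIDUES])
        probs = probs / probs.sum()

    n_dup = int(round(params.duplicate_fraction * params.n_proteins))
    n_frag = int(round(params.fragment_fraction * params.n_proteins))
    n_orig = params.n_proteins - n_dup - n_frag
    if n_orig < 1:
        raise ValueError("parameters leave no original sequences")

    records: list[ProteinRecord] = []
    for i in range(n_orig):
        length = int(np.clip(
            round(rng.lognormal(params.length_log_mean, params.length_log_sigma)),
            params.length_min, params.length_max,
        ))
        records.append(ProteinRecord(
            accession=f"SYN{i + 1:05d}",
            sequence=_random_sequence(rng, length, probs),
            description=f"Synthetic protein {i + 1} OS=Synthetica testata",
            organism="Synthetica testata",
        ))

    duplicate_groups: dict[str, list[str]] = {}
    for j in range(n_dup):
        parent = records[int(rng.integers(0, n_orig))]
        accession = f"SYNDUP{j + 1:04d}"
        records.append(ProteinRecord(
            accession=accession,
            sequence=parent.sequence,
            description=f"Duplicate of {parent.accession}",
        ))
        duplicate_groups.setdefault(parent.accession, [parent.accession]).append(accession)

    fragment_parents: dict[str, str] = {}
    for j in range(n_frag):
        parent = records[int(rng.integers(0, n_orig))]
        keep = int(rng.integers(max(10, len(parent.sequence) // 10),
                                max(11, len(parent.sequence) - 1)))
        accession = f"SYNFRG{j + 1:04d}"
        records.append(ProteinRecord(
            accession=accession,
            sequence=parent.sequence[:keep],
            description=f"Fragment of {parent.accession}",
        ))
        fragment_parents[accession] = parent.accession

    db = ProteinDatabase(records=records, source_label=f"synthetic(seed={params.seed})")
    manifest = {
        "seed": params.seed,
        "n_proteins": params.n_proteins,
        "n_original": n_orig,
        "duplicate_groups": {k: v for k, v in duplicate_groups.items()},
        "fragment_parents": fragment_parents,
    }
    return db, manifest


def sigma_for_ppm_coverage(target_fraction: float, threshold: float = 5.0) -> float:
    """Standard deviation of a centred normal ppm-error distribution such that
    ``P(|error| < threshold)`` equals ``target_fraction``."""
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must be in (0, 1)")
    z = stats.norm.ppf(0.5 + target_fraction / 2.0)
    return threshold / z


@dataclass
class SyntheticRunParams:
    n_replicates: int = 4
    n_true_proteins: int = 100
    abundance_decades: float = 3.0
    detection_midpoint_decade: float = -0.5  # log10 ng at 50% detection
    detection_slope: float = 0.25            # logistic scale in decades
    always_detect: bool = False              # direct-assignment mode for exact tests
    n_peptides: int = 3400
    fraction_missed_cleavage: float = 0.17
    fraction_in_source: float = 0.13
    fraction_pepfrag1: float = 0.58
    fraction_pepfrag2: float = 0.06
    ppm_within_5_target: float = 0.82
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = (self.fraction_missed_cleavage, self.fraction_in_source,
                     self.fraction_pepfrag1, self.fraction_pepfrag2)
        if any(not 0.0 <= f <= 1.0 for f in fractions):
            raise ValueError("match-type fractions must be in [0, 1]")
        if sum(fractions) > 1.0 + 1e-12:
            raise ValueError("match-type fractions sum to more than 1")

    @property
    def match_type_probs(self) -> dict[str, float]:
        remainder = 1.0 - (self.fraction_pepfrag1 + self.fraction_pepfrag2
                           + self.fraction_in_source + self.fraction_missed_cleavage)
        return {
            "PepFrag1": self.fraction_pepfrag1,
            "PepFrag2": self.fraction_pepfrag2,
            "VarMod": remainder / 3.0,
            "InSource": self.fraction_in_source,
            "MissedCleavage": self.fraction_missed_cleavage,
            "NeutralLoss_H2O": remainder / 3.0,
            "NeutralLoss_NH3": remainder / 3.0,
        }


def generate_replicates(
    db: ProteinDatabase, params: SyntheticRunParams
) -> tuple[ReplicateSet, pd.DataFrame, dict]:
    """Simulate per-replicate protein tables and a peptide-hit table.

    True log10 abundances are uniform over ``[min, min + decades]`` with the
    extremes pinned, so the merged dynamic range is the configured decade
    count. Detection per (protein, replicate) follows a logistic curve in
    log10 abundance unless ``always_detect``. Each detected (protein,
    replicate) pair receives at least one peptide hit, so protein and peptide
    tables stay consistent.
    """
    if params.n_true_proteins > len(db):
        raise ValueError("n_true_proteins exceeds database size")
    rng = np.random.default_rng(params.seed)
    records = list(db)[: params.n_true_proteins]
    n = len(records)

    log_ng = rng.uniform(0.0, params.abundance_decades, size=n)
    if n >= 2:  # pin the extremes so the planted range is exact
        log_ng[0], log_ng[1] = params.abundance_decades, 0.0
    ng_true = 10.0 ** log_ng

    if params.always_detect:
        detected = np.ones((n, params.n_replicates), dtype=bool)
    else:
        p = 1.0 / (1.0 + np.exp(-(log_ng - params.detection_midpoint_decade)
                                / params.detection_slope))
        detected = rng.random((n, params.n_replicates)) < p[:, None]
        detected[ng_true >= 10 ** (params.abundance_decades - 0.25), :] = True

    # peptide pool per protein, from an actual tryptic digest
    peptide_pool = {
        r.accession: [p.sequence for p in digest_protein(r, TRYPSIN, max_missed=1)
                      if len(p) >= 4]
        for r in records
    }

    sigma = sigma_for_ppm_coverage(params.ppm_within_5_target, threshold=5.0)
    probs = params.match_type_probs
    type_names = list(MATCH_TYPES)
    type_p = np.array([probs[t] for t in type_names])

    pairs = [(i, rep) for i in range(n) for rep in range(1, params.n_replicates + 1)
             if detected[i, rep - 1]]
    if not pairs:
        raise ValueError("no detections; detection parameters infeasible")
    if params.n_peptides < len(pairs):
        raise ValueError(
            f"n_peptides={params.n_peptides} cannot cover {len(pairs)} detections"
        )

    # one guaranteed hit per detected pair, remainder multinomial by abundance
    weights = np.array([ng_true[i] for i, _ in pairs], dtype=float)
    weights /= weights.sum()
    extra = rng.multinomial(params.n_peptides - len(pairs), weights)
    hit_rows = []
    for (i, rep), extra_hits in zip(pairs, extra):
        accession = records[i].accession
        pool = peptide_pool[accession] or [records[i].sequence]
        count = 1 + int(extra_hits)
        seqs = rng.choice(pool, size=count)
        types = rng.choice(type_names, size=count, p=type_p)
        errors = rng.normal(0.0, sigma, size=count)
        for seq, mtype, err in zip(seqs, types, errors):
            hit_rows.append((str(seq), str(mtype), float(err), accession, rep))
    hits = pd.DataFrame(
        hit_rows, columns=["sequence", "match_type", "ppm_error", "parent_code",
                           "replicate_id"],
    )

    protein_tables: dict[int, pd.DataFrame] = {}
    for rep in range(1, params.n_replicates + 1):
        rows = []
        rep_hits = hits[hits["replicate_id"] == rep]
        for i, record in enumerate(records):
            if not detected[i, rep - 1]:
                continue
            noise = rng.normal(1.0, 0.05)
            n_pep = int((rep_hits["parent_code"] == record.accession).sum())
            rows.append({
                "uniprot_code": record.accession,
                "description": record.description or record.accession,
                "protein_mw": float(100.0 * len(record.sequence)),
                "score": float(1000.0 * ng_true[i] * abs(noise)),
                "products": float(3 * n_pep),
                "peptides": float(n_pep),
                "fmol": float(ng_true[i] * abs(rng.normal(1.0, 0.1))),
                "ng": float(ng_true[i] * abs(noise)),
            })
        protein_tables[rep] = pd.DataFrame(rows)

    manifest = {
        "seed": params.seed,
        "n_replicates": params.n_replicates,
        "true_ng": {records[i].accession: float(ng_true[i]) for i in range(n)},
        "detections": {
            records[i].accession: [int(r + 1) for r in range(params.n_replicates)
                                   if detected[i, r]]
            for i in range(n)
        },
        "repeat_rates": {records[i].accession: int(detected[i].sum()) for i in range(n)},
        "match_type_probs": probs,
        "ppm_sigma": sigma,
        "n_peptide_hits": int(len(hits)),
    }
    return ReplicateSet(protein_tables=protein_tables), hits, manifest


_REFERENCE_TABLE = "seed_protein_table.tsv"


def load_reference_table() -> MergedTable:
    """The packaged 113-row merged soybean-seed identification table,
    values exactly as printed in the source report (four replicates,
    minimum repeat rate 2)."""
    with resources.as_file(
        resources.files("seedscape.data").joinpath(_REFERENCE_TABLE)
    ) as path:
        df = read_protein_table(path, merged=True)
    return MergedTable(df=df, n_replicates=4, min_repeat=2)
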