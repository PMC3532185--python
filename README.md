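# seedscape

Tools for assessing shotgun-proteomics experiments against a protein sequence
database: in-silico protease digestion with missed-cleavage enumeration,
peptide/protein monoisotopic mass and isoelectric-point calculation,
detectability statistics over peptide-mass windows, and merging/quantification
of replicated label-free identification tables (repeat rate, percent of total
soluble protein, dynamic range, functional-category summaries).

A packaged reference table — a merged 113-protein soybean seed identification
table from a four-replicate NanoUPLC-MS<sup>E</sup> experiment — ships with
the package, together with synthetic-data generators that plant known ground
truth so every pipeline stage is testable without external downloads.

## Library overview

| Module | Purpose |
| --- | --- |
| `seedscape.fasta_io` | FASTA read/write, UniProt-style header parsing, duplicate-sequence detection |
| `seedscape.digestion` | cleavage-site enumeration, per-protein and per-database digestion, brute-force oracle |
| `seedscape.physchem` | monoisotopic/average mass, m/z, ppm error, pI by bisection (Bjellqvist or EMBOSS pK sets) |
| `seedscape.db_assessment` | mass-window peptide filters, protein detectability window scans, pI/mass histograms |
| `seedscape.id_tables` | replicate-table parsing, merging (minimum repeat rate), %TSP, dynamic range, keyword and category shares, peptide match-type summaries |
| `seedscape.synthetic_data` | seeded database/replicate generators with ground-truth manifests; `load_reference_table()` |
| `seedscape.pipeline` | `RunConfig` + `run_pipeline` report bundle (TSV tables + JSON summary) |

Example:

```python
from seedscape import read_fasta, digest_database
from seedscape.db_assessment import STANDARD_WINDOWS, window_scan

db = read_fasta("proteins.fasta")
peptides, summary = digest_database(db, max_missed=1)
scan = window_scan(peptides, db.accessions, STANDARD_WINDOWS, ks=[0, 1, 2, 3])
print(scan.counts)
```

## Command line

```sh
seedscape digest  --fasta proteins.fasta --enzyme trypsin --missed 1 --out peptides.tsv
seedscape assess  --fasta proteins.fasta --windows 500:1000,500:5000 --ks 0,1,2,3 --out report/
seedscape merge   --replicates r1.tsv --replicates r2.tsv --replicates r3.tsv \
                  --replicates r4.tsv --min-repeat 2 --out report/
seedscape report  --keywords glycinin --out report/      # uses the packaged reference table
seedscape simulate db  --n 100 --duplicate-fraction 0.1 --seed 1 --out synthetic_db/
seedscape simulate run --n-proteins 100 --n-peptides 3400 --seed 1 --out synthetic_run/
```

Every command writes plain TSV/JSON; `assess`/`merge`/`report` also write a
`summary.json` with the headline statistics.

## Conventions

* Peptide coordinates are 0-based, half-open `[start, end)`.
* Trypsin follows the Keil rule (no cleavage before proline) by default;
  suppression can be disabled (`--no-proline-rule`, `CleavageRule.without_suppression()`).
* Detection windows are open intervals by default (`500:1000` means
  `500 < m < 1000`); closed bounds are available via flags.
* Ambiguous residues (B/J/O/U/X/Z) are retained in sequences but yield
  undefined mass/pI and never count as detectable.
* Reported percentages round half-away-from-zero (two decimals for per-row
  %TSP, integer percent for summary fractions).
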