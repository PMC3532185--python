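"""End-to-end report generation tying the pipeline stages together.

Every figure-level statistic is emitted as TSV/JSON; plots (optional, needs
matplotlib) are a convenience layer over the same numbers.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from seedscape import db_assessment, id_tables
from seedscape.db_assessment import STANDARD_WINDOWS, DetectionWindow
from seedscape.digestion import digest_database, get_rule
from seedscape.fasta_io import read_fasta
from seedscape.id_tables import MergedTable
from seedscape.synthetic_data import load_reference_table

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised with the failing stage named, for a clean nonzero CLI exit."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    fasta: Path | None = None
    replicate_tables: Sequence[Path] = ()
    use_reference_table: bool = False
    enzyme: str = "trypsin"
    max_missed: int = 1
    pkset: str = "bjellqvist"
    windows: Sequence[DetectionWindow] = STANDARD_WINDOWS
    ks: Sequence[int] = (0, 1, 2, 3)
    min_repeat: int = 2
    keywords: Sequence[str] = ("glycinin",)
    compute_pi: bool = False
    out_dir: Path = Path("seedscape_report")
    plots: bool = False

    def validate(self) -> None:
        if self.max_missed < 0:
            raise PipelineError("config", "max_missed must be >= 0")
        if self.min_repeat < 1:
            raise PipelineError("config", "min_repeat must be >= 1")
        if not self.windows:
            raise PipelineError("config", "at least one detection window required")
        get_rule(self.enzyme)
        if self.fasta is not None and not Path(self.fasta).exists():
            raise PipelineError("config", f"FASTA not found: {self.fasta}")
        for p in self.replicate_tables:
            if not Path(p).exists():
                raise PipelineError("config", f"replicate table not found: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and write the report bundle.

    Emits (as applicable): digestion summary, window-scan tables, pI/MW
    histograms, the merged identification table and its repeat-rate / %TSP /
    dynamic-range / category summaries. Returns the JSON summary dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    if config.fasta is not None:
        summary["database_assessment"] = _assess_database(config, out)

    merged = _load_merged(config)
    if merged is not None:
        summary["identification"] = _summarise_merged(config, merged, out)

    with (out / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("report written to %s", out)
    return summary


def _assess_database(config: RunConfig, out: Path) -> dict:
    try:
        db = read_fasta(config.fasta)
    except Exception as exc:
        raise PipelineError("fasta_io", str(exc)) from exc
    log.info("stage fasta_io: %d records", len(db))

    try:
        peptides, digest_summary = digest_database(
            db, get_rule(config.enzyme), config.max_missed,
            compute_pi=config.compute_pi,
        )
    except Exception as exc:
        raise PipelineError("digestion", str(exc)) from exc
    log.info("stage digestion: %d peptide occurrences", len(peptides))
    peptides.to_csv(out / "peptides.tsv", sep="\t", index=False)

    try:
        scan = db_assessment.window_scan(peptides, db.accessions,
                                         config.windows, config.ks)
    except Exception as exc:
        raise PipelineError("db_assessment", str(exc)) from exc
    scan.to_tsv(out / "window_scan.tsv")
    _write_members(scan, out / "window_scan_members.tsv")

    mass_hist = db_assessment.value_distribution(
        peptides["mono_mass"], bin_edges=np.arange(0, 10500, 500),
    )
    mass_hist.to_frame().to_csv(out / "peptide_mass_histogram.tsv", sep="\t", index=False)

    result = {
        "digestion": digest_summary.as_dict(),
        "window_scan": {
            label: {str(k): int(v) for k, v in row.items()}
            for label, row in scan.counts.iterrows()
        },
    }
    if config.compute_pi:
        pi_hist = db_assessment.pi_distribution(peptides["pi"], thresholds=(5.0, 8.0))
        pi_hist.to_frame().to_csv(out / "peptide_pi_histogram.tsv", sep="\t", index=False)
        result["pi_cumulative_below"] = pi_hist.cumulative_below
    if config.plots:
        _plot_histogram(mass_hist, "peptide monoisotopic mass (Da)",
                        out / "peptide_mass_histogram.png")
    return result


def _load_merged(config: RunConfig) -> MergedTable | None:
    if config.replicate_tables:
        try:
            reps = id_tables.ReplicateSet.from_paths(list(config.replicate_tables))
            return id_tables.merge_replicates(reps, config.min_repeat)
        except Exception as exc:
            raise PipelineError("id_tables", str(exc)) from exc
    if config.use_reference_table:
        return load_reference_table()
    return None


def _summarise_merged(config: RunConfig, merged: MergedTable, out: Path) -> dict:
    try:
        df = id_tables.apply_min_repeat(merged.df, config.min_repeat)
        df = id_tables.percent_tsp(df)
        counts, percents = id_tables.repeat_rate_summary(df)
        decades, ratio = id_tables.dynamic_range_logs(df)
        categories = id_tables.classify_function(df)
    except Exception as exc:
        raise PipelineError("id_tables", str(exc)) from exc

    id_tables.write_merged_table(df, out / "merged_table.tsv")
    result = {
        "n_proteins": int(len(df)),
        "repeat_rate_counts": {str(k): v for k, v in counts.items()},
        "repeat_rate_percents": {str(k): v for k, v in percents.items()},
        "dynamic_range_decades": decades,
        "dynamic_range_ratio": ratio,
        "category_share_by_rows": categories.share_by_rows,
        "category_share_by_tsp": categories.share_by_tsp,
        "keyword_tsp_shares": {},
    }
    for keyword in config.keywords:
        share, _ = id_tables.keyword_tsp_share(df, keyword)
        result["keyword_tsp_shares"][keyword] = share
    log.info("stage id_tables: %d proteins, %d decades", len(df), decades)
    return result


def _write_members(scan: db_assessment.WindowScanResult, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("window\tk\tn_proteins\taccessions\n")
        for (label, k), accs in scan.members.items():
            fh.write(f"{label}\t{k}\t{len(accs)}\t{','.join(accs)}\n")


def _plot_histogram(hist: db_assessment.Histogram, xlabel: str, path: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        log.warning("matplotlib unavailable; skipping plot %s", path)
        return
    fig, ax = plt.subplots(figsize=(6, 4))
    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    width = np.diff(hist.bin_edges)
    ax.bar(centers, hist.counts, width=width * 0.9)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
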