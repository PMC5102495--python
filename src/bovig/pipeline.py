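"""Orchestration: run the full workflow and render the HTML report.

The pipeline is pure plumbing over the library: build or load the
germline database, annotate every transcript, scan pass-QC records for
gene-conversion events, compute repertoire statistics, and write TSV
tables, a self-contained HTML report and a machine-readable run
manifest.  Stage outputs are byte-identical whether invoked here or
module by module.
"""

from __future__ import annotations

import hashlib
import html
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import Annotation, SampleRecord, annotate_all, annotations_table
from .geneconv import analyze_record, events_table, region_summary
from .germline import GermlineDatabase
from .stats import (
    cdr3_length_distribution,
    usage_frequencies,
    recombination_table,
    wu_kabat,
)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "render_report"]

MISSING = "."


@dataclass
class RunConfig:
    db_dir: str | Path
    samples_fasta: str | Path
    out_dir: str | Path
    sample_sheet: str | Path | None = None
    d_procedure: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.d_procedure not in (1, 2, 3):
            raise ValueError("D procedure must be 1, 2 or 3")


@dataclass
class RunResult:
    records: list[SampleRecord]
    annotations: list[Annotation]
    events: list
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    out_dir: Path | None = None


def _read_samples(fasta: str | Path, sheet: str | Path | None):
    from Bio import SeqIO

    groups: dict[str, str] = {}
    if sheet is not None:
        df = pd.read_csv(sheet, sep="\t", dtype=str)
        groups = dict(zip(df["id"], df["group"]))
    out = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        group = groups.get(rec.id, "")
        if not group and "group=" in rec.description:
            group = rec.description.split("group=")[1].split()[0]
        out.append((rec.id, group, str(rec.seq)))
    return out


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=MISSING)


def run_pipeline(cfg: RunConfig) -> RunResult:
    """build-db (pre-built) -> annotate -> geneconv -> stats -> report."""
    db_dir = Path(cfg.db_dir)
    if not (db_dir / "db.json").exists():
        raise FileNotFoundError(f"no prepared germline database at {db_dir}")
    db = GermlineDatabase.load(db_dir)
    samples = _read_samples(cfg.samples_fasta, cfg.sample_sheet)
    records, annotations = annotate_all(samples, db, cfg.d_procedure)
    rec_by_id = {r.id: r for r in records}
    events = []
    for ann in annotations:
        events.extend(analyze_record(ann, rec_by_id[ann.sample_id], db))
    groups = {r.id: r.group for r in records}

    tables: dict[str, pd.DataFrame] = {}
    tables["annotations"] = annotations_table(records, annotations)
    tables["events"] = events_table(events)
    tables["event_summary"] = region_summary(events, groups)
    if annotations:
        for axis in ("V", "D", "J"):
            usage = usage_frequencies(annotations, axis)
            tables[f"usage_{axis}"] = usage.percentages().round(2)
        tables["recombinations"] = recombination_table(annotations).counts
        tables["cdr3_lengths"] = cdr3_length_distribution(annotations).round(2)
        profile = wu_kabat([a.position_residues for a in annotations], db.scheme)
        tables["variability"] = profile.table.round(3)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    indexed = {"usage_V", "usage_D", "usage_J", "recombinations",
               "cdr3_lengths", "variability"}
    for name, df in tables.items():
        _write_tsv(df, out / f"{name}.tsv", index=name in indexed)
    (out / "report.html").write_text(render_report(tables))
    manifest = {
        "tool": "bovig",
        "version": __version__,
        "parameters": {
            "d_procedure": cfg.d_procedure,
            "seed": cfg.seed,
        },
        "inputs": {
            "db": str(db_dir),
            "samples": str(cfg.samples_fasta),
            "sample_sheet": str(cfg.sample_sheet) if cfg.sample_sheet else None,
        },
        "outputs": {
            f"{name}.tsv": hashlib.sha256((out / f"{name}.tsv").read_bytes()).hexdigest()
            for name in tables
        },
        "n_records": len(records),
        "n_pass_qc": len(annotations),
        "n_events": len(events),
        "status": "ok",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunResult(records, annotations, events, tables, out)


def render_report(tables: dict[str, pd.DataFrame]) -> str:
    """Render all result tables into one self-contained HTML document."""
    sections = []
    titles = {
        "annotations": "Per-sequence assignments",
        "events": "Putative gene-conversion events",
        "event_summary": "Conversion events per donor, region and group",
        "usage_V": "IGHV usage (%)",
        "usage_D": "IGHD usage (%)",
        "usage_J": "IGHJ usage (%)",
        "recombinations": "V-D-J recombinations",
        "cdr3_lengths": "CDR3H length distribution (%)",
        "variability": "Wu-Kabat variability per IMGT position",
    }
    for name, df in tables.items():
        title = titles.get(name, name)
        sections.append(f"<h2>{html.escape(title)}</h2>")
        if df.empty:
            sections.append("<p><em>no rows</em></p>")
        else:
            sections.append(
                df.to_html(
                    border=0, na_rep=MISSING, float_format=lambda v: f"{v:g}"
                )
            )
    body = "\n".join(sections)
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>bovig report</title>"
        "<style>body{font-family:sans-serif;margin:2em}"
        "table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:2px 6px;font-size:90%}</style>"
        "</head><body>\n<h1>Heavy-chain repertoire annotation report</h1>\n"
        f"{body}\n</body></html>\n"
    )
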