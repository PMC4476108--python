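"""Abundance tables and the end-to-end pipeline driver.

The abundance of a classified contig or singlet is the length of its
best alignment multiplied by the number of reads that went into it.
Abundances are summed per (gene, genus, species); multi-genus calls are
split equally across their listed genera under the species label
"multiple" (the raw assignment table preserves the un-split record).

Because rRNA operon copy number varies between one and about fifteen
per genome, 16S-based shares over-represent high-copy species; the
``exclude_16s`` flag drops 16S/18S from the overall cross-gene table
(per-gene tables are always produced), removing that bias at the cost
of relying on the single-copy protein markers alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .assemble import greedy_assemble, write_contigs
from .classify import TaxAssignment, classify_all, write_assignments
from .recruit import PipelineParams, read_sequences, recruit_reads, write_bins
from .refdb import ReferenceDB

logger = logging.getLogger(__name__)

_COLS = ["gene", "genus", "species", "abundance", "fraction"]


@dataclass
class AbundanceTable:
    """Per-gene and overall abundance summaries.

    ``per_gene`` maps gene -> DataFrame with fractions normalised
    within the gene; ``overall`` aggregates over (genus, species)
    across the included genes.
    """

    per_gene: dict[str, pd.DataFrame] = field(default_factory=dict)
    overall: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_COLS[1:]))

    @property
    def total(self) -> float:
        return float(self.overall["abundance"].sum())


def contig_abundance(assignment: TaxAssignment) -> float:
    """Alignment length times the contig's read count (0 for null calls)."""
    if assignment is None or assignment.is_null:
        return 0.0
    return float(assignment.aln_length * assignment.n_reads)


def aggregate(assignments: list[TaxAssignment],
              exclude_16s: bool = False) -> AbundanceTable:
    """Sum abundances per (gene, genus, species).

    Multi-genus assignments contribute one row per listed genus with
    species "multiple" and the abundance split equally.  When
    ``exclude_16s`` is set, 16S and 18S rows are dropped from the
    overall table only.
    """
    rows = []
    for a in assignments:
        ab = contig_abundance(a)
        if ab == 0.0:
            continue
        if a.status == "unambiguous":
            rows.append((a.gene, a.genus_labels[0], a.species, ab))
        else:
            share = ab / len(a.genus_labels)
            for genus in a.genus_labels:
                rows.append((a.gene, genus, "multiple", share))
    df = pd.DataFrame(rows, columns=_COLS[:4])
    table = AbundanceTable()
    for gene, sub in df.groupby("gene", sort=True):
        g = (sub.groupby(["gene", "genus", "species"], as_index=False)
             ["abundance"].sum())
        g["fraction"] = g["abundance"] / g["abundance"].sum()
        table.per_gene[str(gene)] = g.sort_values(
            "abundance", ascending=False, kind="stable").reset_index(drop=True)
    kept = df if not exclude_16s else df[~df["gene"].isin(["16S", "18S"])]
    overall = (kept.groupby(["genus", "species"], as_index=False)
               ["abundance"].sum())
    total = overall["abundance"].sum()
    overall["fraction"] = overall["abundance"] / total if total else 0.0
    table.overall = overall.sort_values(
        "abundance", ascending=False, kind="stable").reset_index(drop=True)
    return table


def classified_read_share(assignments: list[TaxAssignment],
                          exclude_16s: bool = False) -> pd.Series:
    """Fraction of classified reads attributed to each genus.

    This is the percentage-of-sequences view used for contamination
    screening: every contig contributes its read count to its assigned
    genus (split equally for multi-genus calls), so the result tracks
    read origin directly and is insensitive to how completely each
    species' genes happened to assemble.
    """
    counts: dict[str, float] = {}
    for a in assignments:
        if a.is_null:
            continue
        if exclude_16s and a.gene in ("16S", "18S"):
            continue
        share = a.n_reads / len(a.genus_labels)
        for genus in a.genus_labels:
            counts[genus] = counts.get(genus, 0.0) + share
    total = sum(counts.values())
    ser = pd.Series(counts, dtype=float).sort_values(ascending=False)
    return ser / total if total else ser


def run_pipeline(reads_path: str | Path, db_dir: str | Path,
                 params: PipelineParams,
                 out_dir: str | Path | None = None) -> AbundanceTable:
    """recruit -> assemble -> classify -> aggregate, with artifacts on disk."""
    db = ReferenceDB.load(db_dir)
    reads = read_sequences(reads_path)
    table, _ = analyze_reads(reads, db, params, out_dir)
    return table


def analyze_reads(reads: list[tuple[str, str]], db: ReferenceDB,
                  params: PipelineParams,
                  out_dir: str | Path | None = None
                  ) -> tuple[AbundanceTable, list[TaxAssignment]]:
    """In-memory pipeline core shared by the CLI and the test harness."""
    timings = {}
    t0 = time.perf_counter()
    bins = recruit_reads(reads, db, params)
    timings["recruit_s"] = round(time.perf_counter() - t0, 3)
    t0 = time.perf_counter()
    contigs = []
    for gene in sorted(bins):
        contigs.extend(greedy_assemble(bins[gene], params))
    timings["assemble_s"] = round(time.perf_counter() - t0, 3)
    t0 = time.perf_counter()
    assignments = classify_all(contigs, db, params)
    timings["classify_s"] = round(time.perf_counter() - t0, 3)
    table = aggregate(assignments, exclude_16s=params.exclude_16s)
    if not reads:
        logger.warning("no input reads; tables are empty")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        try:
            write_bins(bins, out)
            by_gene: dict[str, list] = {}
            for c in contigs:
                by_gene.setdefault(c.gene, []).append(c)
            for gene, cs in by_gene.items():
                write_contigs(cs, out / f"{gene}.contigs.fasta",
                              out / f"{gene}.members.tsv")
            write_assignments(assignments, out / "assignments.tsv")
            table.overall.to_csv(out / "abundance_overall.tsv", sep="\t",
                                 index=False)
            for gene, df in table.per_gene.items():
                df.to_csv(out / f"abundance_{gene}.tsv", sep="\t", index=False)
            report = {
                "params": vars(params),
                "n_reads": len(reads),
                "recruited": {g: len(b) for g, b in bins.items()},
                "n_contigs": len(contigs),
                "total_abundance": table.total,
                "timings": timings,
            }
            with open(out / "report.json", "w") as fh:
                json.dump(report, fh, indent=2)
        except Exception:
            for p in out.glob("*"):
                p.unlink()
            raise
    return table, assignments
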