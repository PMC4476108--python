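"""Taxonomic assignment of contigs and singlets.

Each contig is searched against the gene's FULL (redundant) reference
set — MEGABLAST-style nucleotide search for 16S/18S, translated protein
search otherwise — keeping hits with E-value strictly below 1e-10.  The
contig is assigned the genus and species of the top bit-score hit.
When several hits tie at the maximal bit score across more than one
(genus, species), a secondary nucleotide search against the gene's
source nucleotide sequences is run and tied hits whose genus is absent
from that search's top result are excluded; any residual tie is
reported as a multi-genus call with no species.

Bit scores are rounded to 2 decimals before tie detection, emulating
report granularity and avoiding spurious uniqueness from floating-point
noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .alncore import (LocalAlignment, ScoringScheme, SearchSpace,
                      align_nt_both_strands, align_translated)
from .assemble import Contig
from .recruit import PipelineParams
from .refdb import NUCLEOTIDE_GENES, ReferenceDB

logger = logging.getLogger(__name__)


@dataclass
class TaxAssignment:
    """Per-contig taxonomic call.

    ``status`` is "unambiguous" (one genus, species present) or
    "multi_genus" (several genera tied, species None); an unclassified
    contig is a multi_genus call with an empty genus list.
    """

    contig_id: str
    gene: str
    status: str
    genus_labels: list[str]
    species: str | None
    best_hit: LocalAlignment | None
    n_reads: int
    aln_length: int

    @property
    def is_null(self) -> bool:
        return not self.genus_labels


def search_full(contig: Contig, db: ReferenceDB,
                params: PipelineParams) -> list[LocalAlignment]:
    """All hits of a contig against the gene's full redundant set.

    Hits with E-value >= the classification threshold are discarded
    (strict bound); results are sorted by descending bit score, ties by
    subject id.
    """
    refs = db.full.get(contig.gene, [])
    is_nt = contig.gene in NUCLEOTIDE_GENES
    scheme = ScoringScheme.nucleotide() if is_nt else ScoringScheme.protein()
    total = sum(len(r.sequence) for r in refs)
    hits = []
    for ref in refs:
        if is_nt:
            space = SearchSpace(len(contig.consensus), total)
            hit = align_nt_both_strands(contig.consensus, ref.sequence,
                                        scheme, space, contig.contig_id,
                                        ref.record_id)
        else:
            if len(contig.consensus) < 3:
                continue
            space = SearchSpace(len(contig.consensus) // 3, total)
            hit = align_translated(contig.consensus, ref.sequence, scheme,
                                   space, contig.contig_id, ref.record_id)
        if passes_classify_filter(hit.evalue, params):
            hits.append(hit)
    hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
    return hits


def passes_classify_filter(evalue: float, params: PipelineParams) -> bool:
    """Strict classification filter: E-value below 1e-10 by default."""
    return evalue < params.classify_evalue_max


def _top_genera_nt(contig: Contig, gene_refs, params: PipelineParams
                   ) -> set[str] | None:
    """Genera of the top-bit-score hit(s) of a nucleotide re-search.

    Uses each reference's nucleotide sequence (the record itself for
    rRNA genes, the stored source nucleotide sequence for protein
    genes).  Returns None when no nucleotide sequences are available.
    """
    scheme = ScoringScheme.nucleotide()
    pairs = []
    for ref in gene_refs:
        nt = ref.sequence if ref.molecule == "nucleotide" else ref.source_nt
        if nt:
            pairs.append((ref, nt))
    if not pairs:
        return None
    total = sum(len(nt) for _, nt in pairs)
    best_bit = None
    top: set[str] = set()
    for ref, nt in pairs:
        space = SearchSpace(len(contig.consensus), total)
        hit = align_nt_both_strands(contig.consensus, nt, scheme, space,
                                    contig.contig_id, ref.record_id)
        bit = round(hit.bit_score, 2)
        if hit.raw_score == 0:
            continue
        if best_bit is None or bit > best_bit:
            best_bit = bit
            top = {ref.genus}
        elif bit == best_bit:
            top.add(ref.genus)
    return top if best_bit is not None else None


def assign_taxonomy(contig: Contig, hits: list[LocalAlignment],
                    db: ReferenceDB, params: PipelineParams
                    ) -> TaxAssignment:
    """Top-bit-score assignment with two-stage genus tie-breaking."""
    if not hits:
        logger.debug("contig %s: no significant hits", contig.contig_id)
        return TaxAssignment(contig.contig_id, contig.gene, "multi_genus",
                             [], None, None, contig.n_reads, 0)
    top_bit = round(hits[0].bit_score, 2)
    tied = [h for h in hits if round(h.bit_score, 2) == top_bit]
    taxa = {}
    for h in tied:
        rec = db.record(contig.gene, h.subject_id)
        taxa.setdefault(rec.taxon, h)
    if len(taxa) > 1 and contig.gene not in NUCLEOTIDE_GENES:
        # secondary nucleotide search; drop genera absent from its top hit(s)
        top_genera = _top_genera_nt(contig, db.full[contig.gene], params)
        if top_genera:
            kept = {t: h for t, h in taxa.items() if t[0] in top_genera}
            if kept:
                taxa = kept
    if len(taxa) == 1:
        (genus, species), hit = next(iter(taxa.items()))
        return TaxAssignment(contig.contig_id, contig.gene, "unambiguous",
                             [genus], species, hit, contig.n_reads,
                             hit.aln_length)
    genera = sorted({t[0] for t in taxa})
    best = tied[0]
    return TaxAssignment(contig.contig_id, contig.gene, "multi_genus",
                         genera, None, best, contig.n_reads, best.aln_length)


def classify_all(contigs: list[Contig], db: ReferenceDB,
                 params: PipelineParams) -> list[TaxAssignment]:
    """One assignment per contig, order preserved; unclassified retained."""
    return [assign_taxonomy(c, search_full(c, db, params), db, params)
            for c in contigs]


def write_assignments(assignments: list[TaxAssignment],
                      path: str | Path) -> None:
    cols = ("contig_id", "gene", "status", "genera", "species", "bit_score",
            "evalue", "identity", "aln_length", "n_reads")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in assignments:
            h = a.best_hit
            fh.write("\t".join([
                a.contig_id, a.gene, a.status if not a.is_null else "unclassified",
                ";".join(a.genus_labels), a.species or "",
                f"{h.bit_score:.2f}" if h else "",
                f"{h.evalue:.3g}" if h else "",
                f"{h.identity:.4f}" if h else "",
                str(a.aln_length), str(a.n_reads)]) + "\n")
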