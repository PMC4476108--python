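"""Read recruitment: bin input reads by marker gene.

Every read is searched against each gene's non-redundant reference set
(nucleotide alignment on both strands for 16S/18S, six-frame translated
alignment for the protein markers).  A read joins a gene's bin iff its
best hit for that gene has E-value strictly below 1e-5 and identity
strictly above 80% — the recruitment filter.  Recruited reads are stored
forward-oriented with respect to the reference so the assembler can use
ungapped overlaps.

An exact k-mer prefilter (k=11 nucleotide, k=5 amino-acid) gates the
full dynamic programming for speed; the result contract is defined by
full alignment on the gated pairs, and the prefilter can be disabled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._kernels import any_member, kmer_codes
from .alncore import (LocalAlignment, ScoringScheme, SearchSpace,
                      align_nt_both_strands, align_peptides, encode_aa,
                      encode_nt, revcomp, translate_six_frames)
from .refdb import NUCLEOTIDE_GENES, ReferenceDB

logger = logging.getLogger(__name__)

NT_PREFILTER_K = 11
AA_PREFILTER_K = 5


@dataclass
class PipelineParams:
    """All pipeline thresholds in one place.

    Defaults implement the published filter settings: recruitment keeps
    hits with E < 1e-5 and identity > 0.80 (strict bounds), contig
    classification keeps hits with E < 1e-10, reference clustering uses
    90% identity, and assembly requires a 20 bp minimum overlap.
    """

    recruit_evalue_max: float = 1e-5
    recruit_identity_min: float = 0.80
    classify_evalue_max: float = 1e-10
    cluster_identity: float = 0.90
    min_overlap: int = 20
    overlap_identity_min: float = 0.90
    exclude_16s: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.recruit_evalue_max <= 0 or self.classify_evalue_max <= 0:
            raise ValueError("E-value thresholds must be positive")
        if not 0 < self.recruit_identity_min < 1:
            raise ValueError("recruit_identity_min must be in (0,1)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass
class BinMember:
    """A recruited read: oriented sequence plus its best hit and anchor.

    ``anchor`` is the read start projected onto the recruiting
    reference's (nucleotide) coordinates; the assembler uses it to
    restrict overlap placement between reads recruited by the same
    reference.
    """

    read_id: str
    sequence: str  # forward-oriented w.r.t. the reference
    hit: LocalAlignment
    anchor: int = 0


@dataclass
class ReadBin:
    gene: str
    members: list[BinMember] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


class ReadFormatError(ValueError):
    pass


def read_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Load FASTA or FASTQ reads (format auto-detected, qualities ignored).

    Duplicate ids are disambiguated by numeric suffixes.  Malformed
    records raise ReadFormatError naming the offending line.
    """
    from Bio import SeqIO

    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line[0]
                break
    if first == "":
        logger.warning("empty reads file %s", path)
        return []
    if first == ">":
        fmt = "fasta"
    elif first == "@":
        fmt = "fastq"
    else:
        raise ReadFormatError(f"{path}: not FASTA or FASTQ (starts {first!r})")
    reads: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    try:
        for rec in SeqIO.parse(str(path), fmt):
            rid = rec.id
            if rid in seen:
                seen[rid] += 1
                rid = f"{rid}.{seen[rec.id]}"
            else:
                seen[rid] = 0
            reads.append((rid, str(rec.seq).upper()))
    except ValueError as exc:
        line_no = 4 * len(reads) + 1 if fmt == "fastq" else len(reads) + 1
        raise ReadFormatError(
            f"{path}: corrupt {fmt} near record {len(reads) + 1} "
            f"(approx line {line_no}): {exc}") from exc
    return reads


def passes_recruit_filter(hit: LocalAlignment, params: PipelineParams) -> bool:
    """Strict recruitment filter: E below threshold AND identity above."""
    return (hit.evalue < params.recruit_evalue_max
            and hit.identity > params.recruit_identity_min)


class _GeneIndex:
    """Per-gene search state: references, search space, k-mer prefilter."""

    def __init__(self, gene: str, refs, scheme_nt: ScoringScheme,
                 scheme_aa: ScoringScheme):
        self.gene = gene
        self.is_nt = gene in NUCLEOTIDE_GENES
        self.refs = refs
        self.scheme = scheme_nt if self.is_nt else scheme_aa
        total = sum(len(r.sequence) for r in refs)
        self.space = SearchSpace(0, total)  # m filled per query
        if self.is_nt:
            k, base, enc = NT_PREFILTER_K, 5, encode_nt
        else:
            k, base, enc = AA_PREFILTER_K, 25, encode_aa
        self.k, self.base = k, base
        kmers = []
        for r in refs:
            kmers.append(kmer_codes(enc(r.sequence), k, base))
        if kmers:
            allk = np.concatenate(kmers)
            self.kmers = np.unique(allk[allk >= 0])
        else:
            self.kmers = np.empty(0, dtype=np.int64)

    def prefilter_nt(self, codes_fwd: np.ndarray, codes_rev: np.ndarray) -> bool:
        if any_member(kmer_codes(codes_fwd, self.k, self.base), self.kmers):
            return True
        return bool(any_member(kmer_codes(codes_rev, self.k, self.base),
                               self.kmers))

    def frames_passing(self, pep_codes: list[np.ndarray]) -> list[bool]:
        """Which of the six frames share an exact k-mer with the refs."""
        return [bool(any_member(kmer_codes(codes, self.k, self.base),
                                self.kmers)) if codes.shape[0] >= self.k
                else False
                for codes in pep_codes]


def _best_hit(read_id: str, seq: str, index: _GeneIndex,
              peptides: list[str] | None = None,
              frames_mask: list[bool] | None = None
              ) -> LocalAlignment | None:
    """Best alignment of a read against every reference of one gene."""
    best: LocalAlignment | None = None
    for ref in index.refs:
        if index.is_nt:
            space = SearchSpace(len(seq), index.space.n)
            hit = align_nt_both_strands(seq, ref.sequence, index.scheme,
                                        space, read_id, ref.record_id)
        else:
            space = SearchSpace(len(seq) // 3, index.space.n)
            peps = peptides if peptides is not None else \
                translate_six_frames(seq)
            hit = align_peptides(peps, ref.sequence, index.scheme,
                                 space, read_id, ref.record_id,
                                 frames_mask=frames_mask)
        if best is None or hit.raw_score > best.raw_score:
            best = hit
    return best


def _orient_and_anchor(seq: str, hit: LocalAlignment, is_nt: bool) -> BinMember:
    """Forward-orient the read and project its start onto reference coords."""
    if hit.strand == "-":
        oriented = revcomp(seq)
    else:
        oriented = seq
    qs, _ = hit.q_interval
    ss, _ = hit.s_interval
    if is_nt:
        anchor = ss - qs
    else:
        # amino-acid subject coords -> nucleotide offset of the oriented read
        frame_off = abs(hit.frame) - 1
        anchor = 3 * ss - (frame_off + 3 * qs)
    return BinMember(hit.query_id, oriented, hit, anchor)


def recruit_reads(reads: list[tuple[str, str]], db: ReferenceDB,
                  params: PipelineParams,
                  use_prefilter: bool = True) -> dict[str, ReadBin]:
    """Align every read to every gene's non-redundant set and bin it.

    A read may enter several gene bins (each at most once); within a bin
    it is stored forward-oriented relative to its best reference hit.
    """
    if not db.genes:
        raise ValueError("reference database has no genes")
    scheme_nt = ScoringScheme.nucleotide()
    scheme_aa = ScoringScheme.protein()
    indexes = {}
    bins: dict[str, ReadBin] = {}
    need_aa = False
    for gene in db.genes:
        refs = db.nonredundant.get(gene, [])
        bins[gene] = ReadBin(gene)
        if not refs:
            logger.warning("gene %s has an empty non-redundant set", gene)
            continue
        indexes[gene] = _GeneIndex(gene, refs, scheme_nt, scheme_aa)
        need_aa = need_aa or not indexes[gene].is_nt
    for read_id, seq in reads:
        if not seq:
            continue
        codes_fwd = encode_nt(seq)
        codes_rev = encode_nt(revcomp(seq))
        peptides = None
        pep_codes = None
        if need_aa and len(seq) >= 3:
            peptides = translate_six_frames(seq)
            if use_prefilter:
                pep_codes = [encode_aa(p) for p in peptides]
        for gene, index in indexes.items():
            if not index.is_nt and len(seq) < 3:
                continue
            frames_mask = None
            if use_prefilter:
                if index.is_nt:
                    if not index.prefilter_nt(codes_fwd, codes_rev):
                        continue
                else:
                    frames_mask = index.frames_passing(pep_codes)
                    if not any(frames_mask):
                        continue
            hit = _best_hit(read_id, seq, index, peptides, frames_mask)
            if hit is not None and passes_recruit_filter(hit, params):
                bins[gene].members.append(
                    _orient_and_anchor(seq, hit, index.is_nt))
    return bins


def write_bins(bins: dict[str, ReadBin], out_dir: str | Path) -> None:
    """Write one ``<gene>.recruited.fasta`` per gene bin."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for gene, bin_ in bins.items():
        with open(out / f"{gene}.recruited.fasta", "w") as fh:
            for m in bin_.members:
                fh.write(f">{m.read_id}\n{m.sequence}\n")
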