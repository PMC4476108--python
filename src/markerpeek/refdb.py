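"""Marker reference databases: loading, cleaning and clustering.

The pipeline screens reads against a small set of conserved marker
genes: 16S, recA, rpoB and groEL for prokaryotes, and 18S, RAD51, HSP60
and RPB2 to flag eukaryotic (human) contamination.  Each gene's
reference set is kept twice: the full redundant set used for
fine-grained classification, and a non-redundant set of cluster
representatives (greedy clustering at 90% identity, CD-HIT style) used
for fast read recruitment.

Reference FASTA headers carry taxonomy as ``>record_id|genus|species[|strain]``.
For protein markers, the source nucleotide sequence of each record can be
supplied alongside (the classifier's tie-breaking step needs it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import edlib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NUCLEOTIDE_GENES = frozenset({"16S", "18S"})
PROTEIN_GENES = frozenset({"recA", "rpoB", "groEL", "RAD51", "HSP60", "RPB2"})
GENES = NUCLEOTIDE_GENES | PROTEIN_GENES

_NT_RESIDUES = set("ACGTN")
_AA_RESIDUES = set("ARNDCQEGHILKMFPSTWYVX")
_AMBIGUOUS = {"nucleotide": "N", "protein": "X"}


class MarkerFormatError(ValueError):
    """Raised for malformed reference records or headers."""


@dataclass
class MarkerRecord:
    """One marker reference sequence with its taxonomy.

    ``molecule`` is nucleotide for the rRNA genes (16S/18S) and protein
    otherwise; ``source_nt`` optionally carries the nucleotide sequence
    a protein record was translated from.
    """

    record_id: str
    gene: str
    molecule: str
    genus: str
    species: str
    sequence: str
    strain: str | None = None
    source_nt: str | None = None

    def __post_init__(self):
        if self.gene not in GENES:
            raise MarkerFormatError(f"unknown gene {self.gene!r}")
        expected = "nucleotide" if self.gene in NUCLEOTIDE_GENES else "protein"
        if self.molecule != expected:
            raise MarkerFormatError(
                f"gene {self.gene} must be {expected}, got {self.molecule!r}")
        if not self.sequence:
            raise MarkerFormatError(f"record {self.record_id}: empty sequence")
        if not self.genus or not self.species:
            raise MarkerFormatError(
                f"record {self.record_id}: genus and species are required")

    @property
    def taxon(self) -> tuple[str, str]:
        return (self.genus, self.species)

    def ambiguous_fraction(self) -> float:
        amb = _AMBIGUOUS[self.molecule]
        return self.sequence.count(amb) / len(self.sequence)


def parse_header(header: str) -> tuple[str, str, str, str | None]:
    """Split ``record_id|genus|species[|strain]`` header fields."""
    parts = header.split("|")
    if len(parts) < 3 or any(not p for p in parts[:3]):
        raise MarkerFormatError(
            f"header {header!r}: expected 'record_id|genus|species[|strain]'")
    strain = "|".join(parts[3:]) or None
    return parts[0], parts[1], parts[2], strain


def load_marker_fasta(path: str | Path, gene: str, molecule: str,
                      source_nt_path: str | Path | None = None
                      ) -> list[MarkerRecord]:
    """Load one gene's reference FASTA into MarkerRecords.

    Sequences are uppercased; the gene and molecule are stamped from the
    arguments.  ``source_nt_path`` may point to a FASTA of nucleotide
    source sequences keyed by the same record ids (protein genes only).
    """
    source_nt: dict[str, str] = {}
    if source_nt_path is not None:
        for rec in SeqIO.parse(str(source_nt_path), "fasta"):
            rid = parse_header(rec.description.split()[0])[0]
            source_nt[rid] = str(rec.seq).upper()
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, genus, species, strain = parse_header(rec.description.split()[0])
        records.append(MarkerRecord(
            record_id=rid, gene=gene, molecule=molecule,
            genus=genus, species=species, strain=strain,
            sequence=str(rec.seq).upper(),
            source_nt=source_nt.get(rid)))
    if not records:
        logger.warning("no records parsed from %s", path)
    return records


def clean_records(records: list[MarkerRecord], min_len: int, max_len: int,
                  max_ambiguous_frac: float) -> list[MarkerRecord]:
    """Drop duplicate, out-of-length-window and ambiguity-heavy records.

    Exact duplicate sequences collapse to the first occurrence; input
    order is otherwise preserved.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    if not 0 <= max_ambiguous_frac <= 1:
        raise ValueError("max_ambiguous_frac must be in [0, 1]")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.sequence in seen:
            continue
        if not min_len <= len(rec.sequence) <= max_len:
            continue
        if rec.ambiguous_fraction() > max_ambiguous_frac:
            continue
        seen.add(rec.sequence)
        out.append(rec)
    return out


def default_length_window(records: list[MarkerRecord]) -> tuple[int, int]:
    """Length window [0.5*median, 1.5*median] used for curation."""
    if not records:
        return (0, 0)
    lens = sorted(len(r.sequence) for r in records)
    median = lens[len(lens) // 2]
    return (int(0.5 * median), int(1.5 * median) + 1)


def concat_rpob_fragments(records: list[MarkerRecord],
                          pairing: dict[str, str]) -> list[MarkerRecord]:
    """Join split rpoB fragments (B' + B'') into single records.

    Each B' record maps to its same-organism B'' record; the merged
    record carries the B' taxonomy and id, with the B'' sequence
    appended.  Records outside the pairing pass through unchanged.
    """
    by_id = {r.record_id: r for r in records}
    for a, b in pairing.items():
        if a not in by_id or b not in by_id:
            raise MarkerFormatError(
                f"pairing {a!r}->{b!r} references a record not in the input")
        if by_id[a].taxon != by_id[b].taxon:
            raise MarkerFormatError(
                f"pairing {a!r}->{b!r} joins different taxa "
                f"{by_id[a].taxon} vs {by_id[b].taxon}")
    consumed = set(pairing.values())
    out = []
    for rec in records:
        if rec.record_id in consumed:
            continue
        if rec.record_id in pairing:
            other = by_id[pairing[rec.record_id]]
            merged = MarkerRecord(
                record_id=rec.record_id, gene=rec.gene, molecule=rec.molecule,
                genus=rec.genus, species=rec.species, strain=rec.strain,
                sequence=rec.sequence + other.sequence,
                source_nt=(rec.source_nt + other.source_nt
                           if rec.source_nt and other.source_nt else None))
            out.append(merged)
        else:
            out.append(rec)
    return out


def global_identity(a: str, b: str) -> float:
    """Identity of the shorter sequence aligned within the longer.

    Measured as 1 - d/len(shorter) where d is the semi-global (infix)
    edit distance of the shorter sequence against the longer; this is
    the identity-over-shorter convention of greedy incremental
    clustering tools.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    d = edlib.align(short, long_, mode="HW", task="distance")["editDistance"]
    return max(0.0, 1.0 - d / len(short))


def cluster_nonredundant(records: list[MarkerRecord],
                         identity_threshold: float = 0.90
                         ) -> tuple[list[MarkerRecord], dict[str, list[str]]]:
    """Greedy longest-first clustering into representatives + members.

    Records are sorted by descending length (stable); each joins the
    first existing cluster whose representative reaches the identity
    threshold, else founds a new cluster.  Returns the founder records
    and a map representative_id -> member record_ids (founder included).
    """
    if len({(r.gene, r.molecule) for r in records}) > 1:
        raise MarkerFormatError("cannot cluster records of mixed genes")
    order = sorted(records, key=lambda r: -len(r.sequence))
    reps: list[MarkerRecord] = []
    cluster_map: dict[str, list[str]] = {}
    for rec in order:
        placed = False
        for rep in reps:
            if global_identity(rec.sequence, rep.sequence) >= identity_threshold:
                cluster_map[rep.record_id].append(rec.record_id)
                placed = True
                break
        if not placed:
            reps.append(rec)
            cluster_map[rec.record_id] = [rec.record_id]
    return reps, cluster_map


@dataclass
class ReferenceDB:
    """Per-gene full (redundant) and non-redundant marker sets."""

    full: dict[str, list[MarkerRecord]] = field(default_factory=dict)
    nonredundant: dict[str, list[MarkerRecord]] = field(default_factory=dict)
    cluster_map: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.full)

    def record(self, gene: str, record_id: str) -> MarkerRecord:
        for rec in self.full[gene]:
            if rec.record_id == record_id:
                return rec
        raise KeyError(record_id)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for gene in self.full:
            gdir = out / gene
            gdir.mkdir(exist_ok=True)
            _write_fasta(gdir / "full.fasta", self.full[gene])
            _write_fasta(gdir / "nr.fasta", self.nonredundant[gene])
            nt_records = [r for r in self.full[gene] if r.source_nt]
            if nt_records:
                _write_fasta(gdir / "source_nt.fasta", nt_records,
                             use_source_nt=True)
            with open(gdir / "clusters.tsv", "w") as fh:
                for rep, members in self.cluster_map[gene].items():
                    for mem in members:
                        fh.write(f"{rep}\t{mem}\n")

    @classmethod
    def load(cls, db_dir: str | Path) -> "ReferenceDB":
        db = cls()
        root = Path(db_dir)
        for gdir in sorted(p for p in root.iterdir() if p.is_dir()):
            gene = gdir.name
            if gene not in GENES:
                continue
            molecule = "nucleotide" if gene in NUCLEOTIDE_GENES else "protein"
            nt_path = gdir / "source_nt.fasta"
            db.full[gene] = load_marker_fasta(
                gdir / "full.fasta", gene, molecule,
                source_nt_path=nt_path if nt_path.exists() else None)
            db.nonredundant[gene] = load_marker_fasta(
                gdir / "nr.fasta", gene, molecule,
                source_nt_path=nt_path if nt_path.exists() else None)
            cmap: dict[str, list[str]] = {}
            with open(gdir / "clusters.tsv") as fh:
                for line in fh:
                    rep, mem = line.rstrip("\n").split("\t")
                    cmap.setdefault(rep, []).append(mem)
            db.cluster_map[gene] = cmap
        return db


def _write_fasta(path: Path, records: list[MarkerRecord],
                 use_source_nt: bool = False) -> None:
    seqs = []
    for r in records:
        header = f"{r.record_id}|{r.genus}|{r.species}"
        if r.strain:
            header += f"|{r.strain}"
        seq = r.source_nt if use_source_nt else r.sequence
        seqs.append(SeqRecord(Seq(seq), id=header, description=""))
    SeqIO.write(seqs, str(path), "fasta")


def build_reference_db(records_by_gene: dict[str, list[MarkerRecord]],
                       cluster_identity: float = 0.90,
                       clean: bool = True,
                       max_ambiguous_frac: float = 0.05,
                       rpob_pairing: dict[str, str] | None = None
                       ) -> ReferenceDB:
    """Clean, optionally join split rpoB fragments, and cluster each gene."""
    db = ReferenceDB()
    for gene, records in records_by_gene.items():
        if gene == "rpoB" and rpob_pairing:
            records = concat_rpob_fragments(records, rpob_pairing)
        if clean:
            lo, hi = default_length_window(records)
            records = clean_records(records, lo, hi, max_ambiguous_frac)
        reps, cmap = cluster_nonredundant(records, cluster_identity)
        db.full[gene] = records
        db.nonredundant[gene] = reps
        db.cluster_map[gene] = cmap
    return db
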