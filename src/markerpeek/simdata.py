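"""Synthetic references, genomes, reads and contamination series.

The read simulator emulates Illumina-like shotgun data: fixed-length
reads (default 101 bp) drawn from uniform random positions and strands,
with a per-read error count ~ Binomial(read_length, total_error_rate),
error positions drawn from a degree-4 polynomial density over relative
position (default 1 + x^4, i.e. errors grow toward the 3' end), and 4
substitutions for every insertion/deletion.  Ground truth (source
interval, strand, every edit with its base) is recorded per read so the
error model can be audited exactly.

The reference generator builds an ancestral sequence per marker gene
and mutates one copy per species to a requested pairwise divergence;
species genomes embed their marker genes (16S at a configurable copy
number) in random background sequence.  Protein markers are generated
as stop-free open reading frames and stored both as translations and as
their source nucleotide sequences.

Mixtures apportion reads across genomes by largest-remainder rounding,
so a requested fraction series is reproduced without file-level
sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alncore import revcomp, translate_six_frames
from .refdb import NUCLEOTIDE_GENES, MarkerRecord

_BASES = "ACGT"
_STOP_CODONS = {"TAA", "TAG", "TGA"}

DEFAULT_GENE_LENGTHS = {"16S": 1500, "recA": 1059, "rpoB": 3501,
                        "groEL": 1647}


@dataclass
class ReadSimProfile:
    """Illumina-like error profile.

    ``positional_poly`` holds coefficients (c0..c4) of the degree-4
    polynomial p(x) = sum c_k x^k over relative read position x in
    [0, 1]; error positions are drawn with density proportional to it.
    ``sub_to_indel_ratio`` r makes each error a substitution with
    probability r/(r+1), else a length-1 insertion or deletion
    (equiprobable).
    """

    n_reads: int = 1000
    read_length: int = 101
    total_error_rate: float = 0.01
    positional_poly: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0)
    sub_to_indel_ratio: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.read_length < 1 or self.n_reads < 0:
            raise ValueError("read_length >= 1 and n_reads >= 0 required")
        if not 0 <= self.total_error_rate < 1:
            raise ValueError("total_error_rate must be in [0, 1)")
        if self.sub_to_indel_ratio <= 0:
            raise ValueError("sub_to_indel_ratio must be positive")
        if len(self.positional_poly) != 5:
            raise ValueError("positional_poly needs 5 coefficients")
        x = np.linspace(0.0, 1.0, 1001)
        if np.any(self._poly(x) < 0):
            raise ValueError("positional polynomial is negative on [0, 1]")
        if not np.any(self._poly(x) > 0):
            raise ValueError("positional polynomial is identically zero")

    def _poly(self, x: np.ndarray) -> np.ndarray:
        return sum(c * x**k for k, c in enumerate(self.positional_poly))

    def position_weights(self, length: int | None = None) -> np.ndarray:
        L = length or self.read_length
        x = np.arange(L) / max(L - 1, 1)
        w = self._poly(x).astype(float)
        return w / w.sum()


@dataclass
class ReadTruth:
    """Ground truth for one simulated read.

    Edit positions are in pre-indel read coordinates; substitutions and
    insertions record the emitted base so the read can be reconstructed
    exactly from its source interval.
    """

    read_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    subs: list[tuple[int, str]] = field(default_factory=list)
    ins: list[tuple[int, str]] = field(default_factory=list)
    dels: list[int] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    reads: list[ReadTruth] = field(default_factory=list)

    def n_substitutions(self) -> int:
        return sum(len(t.subs) for t in self.reads)

    def n_indels(self) -> int:
        return sum(len(t.ins) + len(t.dels) for t in self.reads)


@dataclass
class MixtureSpec:
    """Mixture components as (genome_id, fraction); fractions sum to 1."""

    components: list[tuple[str, float]]

    def __post_init__(self):
        fracs = [f for _, f in self.components]
        if any(f < 0 for f in fracs):
            raise ValueError("fractions must be >= 0")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, length))


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """Random stop-free reading frame of the given length (multiple of 3)."""
    n_codons = length // 3
    codons = []
    while len(codons) < n_codons:
        c = _random_seq(rng, 3)
        if c not in _STOP_CODONS:
            codons.append(c)
    return "".join(codons)


def _mutate(rng: np.random.Generator, seq: str, n_subs: int,
            protein_frame: bool) -> str:
    """Apply n_subs substitutions at distinct positions.

    In protein frames, substitutions that would create a stop codon are
    redrawn so translations stay full length.
    """
    out = list(seq)
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    for p in positions:
        for _ in range(16):
            alt = _BASES[rng.integers(0, 4)]
            if alt == out[p]:
                continue
            if protein_frame:
                c0 = 3 * (p // 3)
                codon = "".join(out[c0:c0 + 3])
                codon = codon[: p - c0] + alt + codon[p - c0 + 1:]
                if codon in _STOP_CODONS:
                    continue
            out[p] = alt
            break
    return "".join(out)


def make_synthetic_references(n_species: int, divergence: float,
                              gene_lengths: dict[str, int] | None = None,
                              seed: int = 0,
                              copy_16s: list[int] | None = None,
                              genome_length: int = 50_000
                              ) -> tuple[dict[str, list[MarkerRecord]],
                                         dict[str, str]]:
    """Generate per-gene marker references and species genomes.

    Each species' gene copy is mutated by divergence/2 substitutions at
    random positions, giving ~``divergence`` pairwise divergence between
    species.  ``copy_16s`` sets each species' 16S operon copy number
    (default 1).  Returns (records_by_gene, genomes keyed by species id
    "sp<i>"); species i carries taxonomy (Genus<i>, species<i>).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not 0 < divergence < 1:
        raise ValueError("divergence must be in (0, 1)")
    gene_lengths = gene_lengths or dict(DEFAULT_GENE_LENGTHS)
    copy_16s = copy_16s or [1] * n_species
    if len(copy_16s) != n_species:
        raise ValueError("copy_16s must have one entry per species")
    # independent child streams: one for marker sequences, one per species
    # genome layout, so a species' 16S copy number can never perturb any
    # other sequence
    streams = np.random.SeedSequence(seed).spawn(n_species + 1)
    rng = np.random.default_rng(streams[0])
    for gene, L in gene_lengths.items():
        if n_species > 1 and round(divergence / 2 * L) < 2:
            raise ValueError(
                f"divergence {divergence} gives <2 substitutions for "
                f"{gene} (length {L}); species are not distinguishable")
    ancestors = {}
    for gene in sorted(gene_lengths):
        L = gene_lengths[gene]
        if gene in NUCLEOTIDE_GENES:
            ancestors[gene] = _random_seq(rng, L)
        else:
            ancestors[gene] = _random_orf(rng, L)
    records: dict[str, list[MarkerRecord]] = {g: [] for g in sorted(gene_lengths)}
    genomes: dict[str, str] = {}
    for i in range(n_species):
        sp_id = f"sp{i}"
        genus, species = f"Genus{i}", f"species{i}"
        marker_nt: dict[str, str] = {}
        for gene in sorted(gene_lengths):
            anc = ancestors[gene]
            is_nt = gene in NUCLEOTIDE_GENES
            n_subs = round(divergence / 2 * len(anc)) if n_species > 1 else 0
            seq_nt = _mutate(rng, anc, n_subs, protein_frame=not is_nt)
            marker_nt[gene] = seq_nt
            if is_nt:
                rec = MarkerRecord(f"{gene}_{sp_id}", gene, "nucleotide",
                                   genus, species, seq_nt)
            else:
                prot = translate_six_frames(seq_nt)[0]
                rec = MarkerRecord(f"{gene}_{sp_id}", gene, "protein",
                                   genus, species, prot, source_nt=seq_nt)
            records[gene].append(rec)
        grng = np.random.default_rng(streams[1 + i])
        segments = []
        for gene in sorted(gene_lengths):
            n_copies = copy_16s[i] if gene == "16S" else 1
            segments.extend([marker_nt[gene]] * n_copies)
        order = grng.permutation(len(segments))
        segments = [segments[k] for k in order]
        bg_total = genome_length - sum(len(s) for s in segments)
        if bg_total < 0:
            raise ValueError("genome_length too small for the marker genes")
        cuts = np.sort(grng.integers(0, bg_total + 1, len(segments)))
        bg = _random_seq(grng, bg_total)
        parts = []
        prev = 0
        for seg, cut in zip(segments, cuts):
            parts.append(bg[prev:cut])
            parts.append(seg)
            prev = cut
        parts.append(bg[prev:])
        genomes[sp_id] = "".join(parts)
    return records, genomes


def sample_error_positions(profile: ReadSimProfile, k: int,
                           rng: np.random.Generator | None = None,
                           length: int | None = None) -> np.ndarray:
    """Draw k error positions (independent, with replacement) from the
    profile's positional polynomial density."""
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = rng or np.random.default_rng(profile.seed)
    L = length or profile.read_length
    if k == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(L, size=k, replace=True, p=profile.position_weights(L))


def _apply_edits(fragment: str, subs, ins, dels) -> str:
    out = list(fragment)
    edits = ([(p, "S", b) for p, b in subs] + [(p, "I", b) for p, b in ins]
             + [(p, "D", "") for p in dels])
    for p, kind, base in sorted(edits, reverse=True):
        if kind == "S":
            out[p] = base
        elif kind == "I":
            out.insert(p, base)
        else:
            del out[p]
    return "".join(out)


def reconstruct_read(truth: ReadTruth, genomes: dict[str, str]) -> str:
    """Replay a truth record's edits onto its source interval."""
    frag = genomes[truth.genome_id][truth.start:truth.end]
    if truth.strand == "-":
        frag = revcomp(frag)
    return _apply_edits(frag, truth.subs, truth.ins, truth.dels)


def simulate_reads(genome: str, profile: ReadSimProfile,
                   rng: np.random.Generator | None = None,
                   genome_id: str = "genome",
                   id_prefix: str = "r") -> tuple[list[tuple[str, str]],
                                                  SyntheticTruth]:
    """Simulate profile.n_reads reads with recorded ground truth.

    Reads have pre-indel length ``read_length``; insertions/deletions
    shift the emitted length by +/-1 each.
    """
    L = profile.read_length
    if len(genome) < L:
        raise ValueError("genome shorter than the read length")
    rng = rng or np.random.default_rng(profile.seed)
    n = profile.n_reads
    starts = rng.integers(0, len(genome) - L + 1, n)
    strands = rng.integers(0, 2, n)
    n_errors = rng.binomial(L, profile.total_error_rate, n)
    p_sub = profile.sub_to_indel_ratio / (profile.sub_to_indel_ratio + 1.0)
    weights = profile.position_weights(L)
    reads = []
    truth = SyntheticTruth()
    for i in range(n):
        start = int(starts[i])
        strand = "-" if strands[i] else "+"
        frag = genome[start:start + L]
        if strand == "-":
            frag = revcomp(frag)
        rt = ReadTruth(f"{id_prefix}{i}", genome_id, start, start + L, strand)
        k = int(n_errors[i])
        if k:
            positions = np.unique(rng.choice(L, size=k, replace=True,
                                             p=weights))
            kinds = rng.random(positions.shape[0])
            which = rng.random(positions.shape[0])
            for p, u, v in zip(positions, kinds, which):
                p = int(p)
                if u < p_sub:
                    alt = _BASES[(_BASES.index(frag[p]) +
                                  int(rng.integers(1, 4))) % 4] \
                        if frag[p] in _BASES else _BASES[rng.integers(0, 4)]
                    rt.subs.append((p, alt))
                elif v < 0.5:
                    rt.ins.append((p, _BASES[rng.integers(0, 4)]))
                else:
                    rt.dels.append(p)
            seq = _apply_edits(frag, rt.subs, rt.ins, rt.dels)
        else:
            seq = frag
        reads.append((rt.read_id, seq))
        truth.reads.append(rt)
    return reads, truth


def largest_remainder_counts(fractions: list[float], n: int) -> list[int]:
    """Apportion n items to fractions exactly (largest-remainder method)."""
    raw = [f * n for f in fractions]
    base = [int(x) for x in raw]
    short = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: (base[i] - raw[i], i))
    for i in order[:short]:
        base[i] += 1
    return base


def make_mixture(genomes: dict[str, str], spec: MixtureSpec,
                 profile: ReadSimProfile
                 ) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Mix reads from several genomes at exact fractions, shuffled."""
    for gid, _ in spec.components:
        if gid not in genomes:
            raise KeyError(f"mixture component {gid!r} has no genome")
    rng = np.random.default_rng(profile.seed)
    counts = largest_remainder_counts([f for _, f in spec.components],
                                      profile.n_reads)
    reads: list[tuple[str, str]] = []
    truth = SyntheticTruth()
    for (gid, _), count in zip(spec.components, counts):
        if count == 0:
            continue
        sub_profile = ReadSimProfile(
            n_reads=count, read_length=profile.read_length,
            total_error_rate=profile.total_error_rate,
            positional_poly=profile.positional_poly,
            sub_to_indel_ratio=profile.sub_to_indel_ratio,
            seed=profile.seed)
        r, t = simulate_reads(genomes[gid], sub_profile, rng=rng,
                              genome_id=gid, id_prefix=f"{gid}_r")
        reads.extend(r)
        truth.reads.extend(t.reads)
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth.reads = [truth.reads[i] for i in order]
    return reads, truth


def contamination_fractions() -> list[float]:
    """The contamination series: 0-5% by 1%, then 5% steps up to 100%."""
    pct = list(range(0, 6)) + list(range(10, 101, 5))
    return [p / 100 for p in pct]


def mixture_series(genomes: dict[str, str], dominant: str, contaminant: str,
                   profile: ReadSimProfile,
                   fractions: list[float] | None = None):
    """Yield (contaminant_fraction, reads, truth) along the series."""
    for i, frac in enumerate(fractions or contamination_fractions()):
        file_profile = ReadSimProfile(
            n_reads=profile.n_reads, read_length=profile.read_length,
            total_error_rate=profile.total_error_rate,
            positional_poly=profile.positional_poly,
            sub_to_indel_ratio=profile.sub_to_indel_ratio,
            seed=profile.seed + i)
        spec = MixtureSpec([(dominant, 1.0 - frac), (contaminant, frac)])
        reads, truth = make_mixture(genomes, spec, file_profile)
        yield frac, reads, truth


def trim_reads(reads: list[tuple[str, str]],
               length: int) -> list[tuple[str, str]]:
    """Truncate each read to its first ``length`` bases."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return [(rid, seq[:length]) for rid, seq in reads]


def write_fastq(reads: list[tuple[str, str]], path: str | Path,
                quality_char: str = "?") -> None:
    """Write reads as FASTQ with a constant Q30 placeholder quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")
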