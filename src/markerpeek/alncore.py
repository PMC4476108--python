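"""Local alignment with Karlin-Altschul bit-score/E-value statistics.

This module provides the shared alignment engine for read recruitment and
contig classification: optimal Smith-Waterman local alignment of
nucleotide sequences (both strands) and of reads translated in six frames
against protein references, plus the bit-score and E-value transforms
that make the pipeline's significance thresholds meaningful.

Raw alignment scores S are converted to bits via

    S' = (lambda * S - ln K) / ln 2

and the expected number of chance hits of at least that score in an
m-by-n search space is

    E = m * n * 2**(-S')

Default scoring follows BLAST-family conventions: nucleotide match +1 /
mismatch -2 with gap -5/-2 (lambda=0.625, K=0.41), and BLOSUM62 with gap
-11/-1 for proteins (lambda=0.267, K=0.041).  No edge-effect length
adjustment is applied to the search space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

from ._kernels import sw_affine

NT_ALPHABET = "ACGTN"
# matches the Biopython BLOSUM62 alphabet
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"

_NT_CODE = np.full(128, 4, dtype=np.uint8)  # unknown -> N
for _i, _c in enumerate(NT_ALPHABET):
    _NT_CODE[ord(_c)] = _i
    _NT_CODE[ord(_c.lower())] = _i

_AA_CODE = np.full(128, AA_ALPHABET.index("X"), dtype=np.uint8)
for _i, _c in enumerate(AA_ALPHABET):
    _AA_CODE[ord(_c)] = _i
    _AA_CODE[ord(_c.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode_nt(seq: str) -> np.ndarray:
    return _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]

def encode_aa(seq: str) -> np.ndarray:
    return _AA_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]

def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution/gap scores plus the Karlin-Altschul parameters.

    ``match``/``mismatch`` drive nucleotide alignments; protein
    alignments use the named substitution matrix instead.  A gap of
    length L contributes ``gap_open + L * gap_extend`` (both negative).
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    lambda_: float = 0.625
    k_: float = 0.41
    protein_matrix: str = "BLOSUM62"

    def __post_init__(self):
        if not self.lambda_ > 0:
            raise ValueError("lambda_ must be positive")
        if not 0 < self.k_ < 1:
            raise ValueError("k_ must be in (0, 1)")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")

    @classmethod
    def nucleotide(cls) -> "ScoringScheme":
        return cls()

    @classmethod
    def protein(cls) -> "ScoringScheme":
        return cls(match=4, mismatch=-4, gap_open=-11, gap_extend=-1,
                   lambda_=0.267, k_=0.041)

    @property
    def nt_matrix(self) -> np.ndarray:
        return _nt_matrix(self.match, self.mismatch)

    @property
    def aa_matrix(self) -> np.ndarray:
        return _aa_matrix(self.protein_matrix)


@lru_cache(maxsize=None)
def _nt_matrix(match: int, mismatch: int) -> np.ndarray:
    mat = np.full((5, 5), mismatch, dtype=np.int32)
    for i in range(4):
        mat[i, i] = match
    mat[4, :] = mismatch  # N never matches, not even itself
    mat[:, 4] = mismatch
    return mat


@lru_cache(maxsize=None)
def _aa_matrix(name: str) -> np.ndarray:
    bio = substitution_matrices.load(name)
    if str(bio.alphabet) != AA_ALPHABET:
        raise ValueError(f"matrix {name} has unexpected alphabet")
    return np.asarray(bio, dtype=np.int32)


@dataclass(frozen=True)
class SearchSpace:
    """Karlin-Altschul search space: query length m, database length n."""

    m: int
    n: int

    def __post_init__(self):
        if self.m < 0 or self.n < 0:
            raise ValueError("search space dimensions must be >= 0")


@dataclass
class LocalAlignment:
    """A scored local hit between a query and a subject sequence.

    Intervals are 0-based half-open.  For minus-strand nucleotide hits
    the query interval refers to the reverse-complemented (oriented)
    query; subject intervals are always on the forward subject.  For
    translated hits the intervals and identity are in amino-acid units
    and ``frame`` records the translation frame of the oriented read.
    """

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    identity: float
    aln_length: int
    q_interval: tuple[int, int]
    s_interval: tuple[int, int]
    strand: str = "+"
    frame: int = 0


def bit_score(raw_score: float, scheme: ScoringScheme) -> float:
    """Normalised score in bits: (lambda*S - ln K) / ln 2."""
    return (scheme.lambda_ * raw_score - math.log(scheme.k_)) / math.log(2.0)


def evalue(bit: float, space: SearchSpace) -> float:
    """Expected chance hits at >= bit score in an m x n search space."""
    return space.m * space.n * 2.0 ** (-bit)


def smith_waterman(query: str, subject: str, scheme: ScoringScheme,
                   molecule: str = "nucleotide",
                   space: SearchSpace | None = None,
                   query_id: str = "query",
                   subject_id: str = "subject") -> LocalAlignment:
    """Optimal local alignment of two sequences under the scheme.

    Traceback ties are broken diagonal > up > left so results are
    deterministic.  When no cell scores positive the returned alignment
    has raw_score 0, empty intervals and identity 0.
    """
    if not query or not subject:
        raise ValueError("cannot align empty sequences")
    if molecule == "nucleotide":
        q, s = encode_nt(query), encode_nt(subject)
        sub = scheme.nt_matrix
    elif molecule == "protein":
        q, s = encode_aa(query), encode_aa(subject)
        sub = scheme.aa_matrix
    else:
        raise ValueError(f"unknown molecule {molecule!r}")
    raw, qs, qe, ss, se, matches, columns = sw_affine(
        q, s, sub, scheme.gap_open, scheme.gap_extend)
    bit = bit_score(raw, scheme)
    if space is None:
        space = SearchSpace(len(query), len(subject))
    return LocalAlignment(
        query_id=query_id, subject_id=subject_id,
        raw_score=int(raw), bit_score=bit, evalue=evalue(bit, space),
        identity=(matches / columns) if columns else 0.0,
        aln_length=int(columns),
        q_interval=(int(qs), int(qe)), s_interval=(int(ss), int(se)))


def align_nt_both_strands(query: str, subject: str, scheme: ScoringScheme,
                          space: SearchSpace | None = None,
                          query_id: str = "query",
                          subject_id: str = "subject") -> LocalAlignment:
    """Best of forward and reverse-complement alignments; ties go to '+'."""
    fwd = smith_waterman(query, subject, scheme, "nucleotide", space,
                         query_id, subject_id)
    rev = smith_waterman(revcomp(query), subject, scheme, "nucleotide", space,
                         query_id, subject_id)
    if rev.raw_score > fwd.raw_score:
        rev.strand = "-"
        return rev
    fwd.strand = "+"
    return fwd


_TABLE11 = unambiguous_dna_by_id[11]
_CODON_AA = np.full(125, _AA_CODE[ord("X")], dtype=np.uint8)  # 5*5*5 codons
for _c1 in range(4):
    for _c2 in range(4):
        for _c3 in range(4):
            _codon = NT_ALPHABET[_c1] + NT_ALPHABET[_c2] + NT_ALPHABET[_c3]
            _aa = _TABLE11.forward_table.get(_codon, "*")
            _CODON_AA[_c1 * 25 + _c2 * 5 + _c3] = _AA_CODE[ord(_aa)]

_AA_CHARS = np.frombuffer(AA_ALPHABET.encode("ascii"), dtype=np.uint8)


def _translate_codes(codes: np.ndarray) -> str:
    n = codes.shape[0] // 3
    if n == 0:
        return ""
    c = codes[: n * 3].reshape(n, 3).astype(np.int32)
    idx = c[:, 0] * 25 + c[:, 1] * 5 + c[:, 2]
    return _AA_CHARS[_CODON_AA[idx]].tobytes().decode("ascii")


def translate_six_frames(read: str, code: int = 11) -> list[str]:
    """Translate in frames +1,+2,+3,-1,-2,-3 (bacterial/plastid code).

    Stop codons are rendered as '*'; trailing partial codons are dropped.
    """
    if code != 11:
        raise ValueError("only translation table 11 is supported")
    if len(read) < 3:
        raise ValueError("read shorter than one codon")
    fwd = encode_nt(read)
    rev = encode_nt(revcomp(read))
    return [_translate_codes(fwd), _translate_codes(fwd[1:]),
            _translate_codes(fwd[2:]), _translate_codes(rev),
            _translate_codes(rev[1:]), _translate_codes(rev[2:])]


_FRAME_ORDER = (1, 2, 3, -1, -2, -3)


def align_translated(read: str, protein_ref: str, scheme: ScoringScheme,
                     space: SearchSpace | None = None,
                     query_id: str = "query",
                     subject_id: str = "subject") -> LocalAlignment:
    """Best protein-level local alignment of the read over six frames.

    A single contiguous correctly-framed segment carries the hit; reads
    with internal frameshifts are scored by their best intact frame.
    Identity is amino-acid identity; the winning frame is recorded and
    earlier frames win ties (order +1,+2,+3,-1,-2,-3).
    """
    return align_peptides(translate_six_frames(read), protein_ref, scheme,
                          space, query_id, subject_id)


def align_peptides(peptides: list[str], protein_ref: str,
                   scheme: ScoringScheme,
                   space: SearchSpace | None = None,
                   query_id: str = "query",
                   subject_id: str = "subject",
                   frames_mask: list[bool] | None = None) -> LocalAlignment:
    """As align_translated but from pre-translated frame peptides.

    ``frames_mask`` optionally restricts which of the six frames are
    scored (used by the recruitment prefilter).
    """
    best: LocalAlignment | None = None
    best_frame = 0
    for idx, (frame, pep) in enumerate(zip(_FRAME_ORDER, peptides)):
        if not pep:
            continue
        if frames_mask is not None and not frames_mask[idx]:
            continue
        if space is None:
            frame_space = SearchSpace(len(pep), len(protein_ref))
        else:
            frame_space = space
        hit = smith_waterman(pep, protein_ref, scheme, "protein", frame_space,
                             query_id, subject_id)
        if best is None or hit.raw_score > best.raw_score:
            best = hit
            best_frame = frame
    if best is None:
        raise ValueError("read too short to translate in any frame")
    best.frame = best_frame
    best.strand = "+" if best_frame > 0 else "-"
    return best
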