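import numpy as np
import pytest

from markerpeek.alncore import LocalAlignment
from markerpeek.recruit import BinMember, ReadBin
from markerpeek.refdb import MarkerRecord, build_reference_db
from markerpeek.simdata import make_synthetic_references

# ---------------------------------------------------------------- oracles


def oracle_local_score(a: str, b: str, match=1, mismatch=-2,
                       gap_open=-5, gap_extend=-2) -> int:
    """Brute-force affine-gap local alignment score (Gotoh recurrences
    written directly from the definition; no traceback, no shortcuts).
    A gap of length L scores gap_open + L*gap_extend."""
    m, n = len(a), len(b)
    NEG = -10**9
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend,
                          H[i][j - 1] + gap_open + gap_extend)
            F[i][j] = max(F[i - 1][j] + gap_extend,
                          H[i - 1][j] + gap_open + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def oracle_infix_edit_distance(short: str, long_: str) -> int:
    """Brute-force semi-global edit distance: the shorter sequence
    aligned anywhere inside the longer (free end gaps in the longer)."""
    m, n = len(short), len(long_)
    prev = [0] * (n + 1)  # free start in long_
    for i in range(1, m + 1):
        cur = [i] * (n + 1)
        for j in range(1, n + 1):
            cost = 0 if short[i - 1] == long_[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def two_species():
    """Two synthetic species at 10% marker divergence plus their db."""
    records, genomes = make_synthetic_references(2, 0.10, seed=11)
    db = build_reference_db(records, clean=False)
    return records, genomes, db


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_bin(gene: str, reads: list[tuple[str, str]]) -> ReadBin:
    """A ReadBin without recruitment metadata (forces exhaustive overlap
    search in the assembler)."""
    return ReadBin(gene, [BinMember(rid, seq, None) for rid, seq in reads])


def dummy_hit(query_id="q", subject_id="s", raw=100, bit=100.0, ev=1e-20,
              identity=1.0, length=100) -> LocalAlignment:
    return LocalAlignment(query_id, subject_id, raw, bit, ev, identity,
                          length, (0, length), (0, length))


def marker_concat(records_by_gene, suffix: str) -> str:
    """Concatenate one species' marker nucleotide sequences."""
    parts = []
    for gene in sorted(records_by_gene):
        for rec in records_by_gene[gene]:
            if rec.record_id.endswith(suffix):
                parts.append(rec.source_nt or rec.sequence)
    return "".join(parts)
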