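"""Greedy overlap-consensus assembly of recruited reads.

Each gene's bin of oriented reads is assembled into contigs by
repeatedly merging the highest-scoring qualifying ungapped overlap
(dovetail or containment) among the current sequences until none
remains.  An overlap qualifies when it spans at least ``min_overlap``
columns (default 20 bp) at identity >= ``overlap_identity_min``
(default 0.90).  Candidate overlaps are ranked by identity*length, then
length, then read id, so assembly is deterministic.  The consensus at
each column is the majority base over the covering reads, ties going to
the earliest-placed read's base.  Reads that never merge survive as
singlet contigs and are still classified downstream.

Gapped overlaps are not modelled: a read whose indels prevent any
qualifying ungapped overlap becomes a singlet.  For large bins whose
members carry recruitment anchors (reference-projected start
positions), overlap placement is restricted to a +/-16 bp band around
the anchor-predicted offset, and only reads recruited by the same
reference are considered against each other.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from ._kernels import scan_one_vs_many, scan_overlap
from .alncore import NT_ALPHABET, encode_nt
from .recruit import PipelineParams, ReadBin

ANCHOR_BAND = 16
_FULL_RANGE = 10**9


@dataclass
class Overlap:
    """A qualifying ungapped overlap: b placed at ``offset`` on a."""

    read_a: str
    read_b: str
    length: int
    identity: float
    offset: int


@dataclass
class Contig:
    """Consensus sequence plus its ordered member reads (offset = placement)."""

    contig_id: str
    gene: str
    consensus: str
    members: list[tuple[str, int]]

    @property
    def n_reads(self) -> int:
        return len(self.members)


def find_overlap(a: str, b: str, min_overlap: int,
                 min_identity: float = 0.90,
                 id_a: str = "a", id_b: str = "b") -> Overlap | None:
    """Best qualifying ungapped overlap of two sequences, or None."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    found, off, length, matches = scan_overlap(
        encode_nt(a), encode_nt(b), min_overlap, min_identity,
        -_FULL_RANGE, _FULL_RANGE)
    if not found:
        return None
    return Overlap(id_a, id_b, int(length), matches / length, int(off))


def consensus_column(bases: list[str]) -> str:
    """Majority base of one column; ties resolved by the earliest-placed
    read's base (first entry whose base is among the tied maxima)."""
    if not bases:
        raise ValueError("empty consensus column")
    counts: dict[str, int] = {}
    for b in bases:
        counts[b] = counts.get(b, 0) + 1
    top = max(counts.values())
    for b in bases:
        if counts[b] == top:
            return b
    raise AssertionError("unreachable")


class _Node:
    """An active sequence during assembly: a read or a partial contig."""

    __slots__ = ("codes", "counts", "first", "members", "anchor", "tie_id")

    def __init__(self, codes, counts, first, members, anchor, tie_id):
        self.codes = codes
        self.counts = counts
        self.first = first
        self.members = members
        self.anchor = anchor
        self.tie_id = tie_id

    @classmethod
    def from_read(cls, read_id: str, seq: str, anchor: int | None) -> "_Node":
        codes = encode_nt(seq)
        return cls(codes, None, None, [(read_id, 0)], anchor, read_id)

    def counts_or_onehot(self) -> np.ndarray:
        if self.counts is not None:
            return self.counts
        onehot = np.zeros((self.codes.shape[0], 5), dtype=np.int32)
        onehot[np.arange(self.codes.shape[0]), self.codes] = 1
        return onehot

    def first_or_codes(self) -> np.ndarray:
        return self.first if self.first is not None else self.codes

    def __len__(self) -> int:
        return self.codes.shape[0]


def _merge(a: _Node, b: _Node, offset: int) -> _Node:
    shift_a = max(0, -offset)
    shift_b = offset + shift_a
    new_len = max(shift_a + len(a), shift_b + len(b))
    counts = np.zeros((new_len, 5), dtype=np.int32)
    counts[shift_a:shift_a + len(a)] += a.counts_or_onehot()
    counts[shift_b:shift_b + len(b)] += b.counts_or_onehot()
    # earliest-placed base per column: a's members were placed before b's
    first = np.full(new_len, 255, dtype=np.uint8)
    fb = b.first_or_codes()
    first[shift_b:shift_b + len(b)] = fb
    fa = a.first_or_codes()
    first[shift_a:shift_a + len(a)] = fa
    top = counts.max(axis=1)
    is_max = counts == top[:, None]
    rows = np.arange(new_len)
    first_clip = np.minimum(first, 4)
    consensus = np.where(is_max[rows, first_clip], first_clip,
                         np.argmax(is_max, axis=1)).astype(np.uint8)
    members = ([(rid, off + shift_a) for rid, off in a.members]
               + [(rid, off + shift_b) for rid, off in b.members])
    anchor = None if a.anchor is None else a.anchor - shift_a
    return _Node(consensus, counts, first.astype(np.uint8), members,
                 anchor, min(a.tie_id, b.tie_id))


def greedy_assemble(bin_: ReadBin, params: PipelineParams,
                    anchored: bool | None = None) -> list[Contig]:
    """Assemble one gene bin into contigs (singlets included).

    ``anchored=None`` enables anchor-banded overlap search automatically
    when every member carries a recruitment anchor; pass False to force
    the exhaustive all-offsets search.
    """
    if anchored is None:
        anchored = bool(bin_.members) and all(
            m.hit is not None for m in bin_.members)
    # partition: reads recruited by different references cannot overlap
    partitions: dict[str, list] = {}
    for m in bin_.members:
        key = m.hit.subject_id if (anchored and m.hit is not None) else ""
        partitions.setdefault(key, []).append(m)
    contigs: list[Contig] = []
    serial = 0
    for key in sorted(partitions):
        nodes = _assemble_partition(partitions[key], params, anchored)
        for node in nodes:
            contigs.append(Contig(
                contig_id=f"{bin_.gene}_c{serial}", gene=bin_.gene,
                consensus="".join(NT_ALPHABET[c] for c in node.codes),
                members=node.members))
            serial += 1
    return contigs


def _assemble_partition(members, params: PipelineParams,
                        anchored: bool) -> list[_Node]:
    from numba.typed import List as NumbaList

    min_ov = params.min_overlap
    min_id = params.overlap_identity_min
    nodes: dict[int, _Node] = {}
    for m in members:
        nodes[len(nodes)] = _Node.from_read(
            m.read_id, m.sequence, m.anchor if anchored else None)
    if not nodes:
        return []
    n0 = len(nodes)
    cap = n0 * 2  # reads + every possible merge product
    codes_list = NumbaList()
    anchors = np.zeros(cap, dtype=np.int64)
    for i in range(n0):
        codes_list.append(nodes[i].codes)
        anchors[i] = nodes[i].anchor or 0
    alive = set(nodes)
    heap: list = []

    def push_batch(new_id: int, others: list[int]) -> None:
        """Evaluate node new_id against the listed nodes and push hits."""
        if not others:
            return
        idx = np.asarray(others, dtype=np.int64)
        b = nodes[new_id]
        found, offs, lens, matches = scan_one_vs_many(
            b.codes, anchors[new_id], codes_list, anchors, idx,
            min_ov, min_id, ANCHOR_BAND, anchored)
        tie_b = b.tie_id
        for t in range(idx.shape[0]):
            if found[t]:
                i = int(idx[t])
                heapq.heappush(heap, (-int(matches[t]), -int(lens[t]),
                                      nodes[i].tie_id, tie_b, i, new_id,
                                      int(offs[t])))

    for j in range(1, n0):
        push_batch(j, list(range(j)))
    while heap:
        _, _, _, _, i, j, off = heapq.heappop(heap)
        if i not in alive or j not in alive:
            continue
        merged = _merge(nodes[i], nodes[j], off)
        alive.discard(i)
        alive.discard(j)
        new_id = len(nodes)
        nodes[new_id] = merged
        codes_list.append(merged.codes)
        anchors[new_id] = merged.anchor or 0
        push_batch(new_id, sorted(alive))
        alive.add(new_id)
    # deterministic output order: by earliest member placement order
    order = sorted(alive, key=lambda k: nodes[k].tie_id)
    return [nodes[k] for k in order]


def write_contigs(contigs: list[Contig], fasta_path, membership_path) -> None:
    """Contig FASTA (header carries n_reads) + membership TSV."""
    with open(fasta_path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.contig_id} n_reads={c.n_reads}\n{c.consensus}\n")
    with open(membership_path, "w") as fh:
        for c in contigs:
            for rid, off in c.members:
                fh.write(f"{c.contig_id}\t{rid}\t{off}\n")
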