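"""Numba-compiled inner loops for local alignment and overlap detection.

Sequences are pre-encoded as uint8 code arrays (see alncore for the
alphabets).  Everything in here is deliberately free of Python objects so
the hot paths stay in compiled code.
"""

import numpy as np
from numba import njit

NEG_INF = np.int32(-(10**9))


@njit(cache=True)
def sw_affine(q, s, sub, gap_open, gap_extend):
    """Optimal local alignment score + traceback under affine gaps (Gotoh).

    A gap of length L scores gap_open + L*gap_extend (both arguments are
    negative).  Ties in the traceback are resolved diagonal > up > left;
    among equal-scoring end cells the one with the smallest query index,
    then smallest subject index, is chosen.

    Returns (score, q_start, q_end, s_start, s_end, matches, columns)
    with 0-based half-open intervals.  A score of 0 means no positive
    local alignment exists and the intervals are empty.
    """
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = E[i, j - 1] + gap_extend
            e2 = H[i, j - 1] + gap_open + gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = F[i - 1, j] + gap_extend
            f2 = H[i - 1, j] + gap_open + gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[qi, s[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback
    i = bi
    j = bj
    matches = 0
    columns = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        h = H[i, j]
        if h == H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]:
            if q[i - 1] == s[j - 1]:
                matches += 1
            columns += 1
            i -= 1
            j -= 1
        elif h == F[i, j]:
            # walk the vertical gap chain
            while True:
                columns += 1
                stop = F[i, j] == H[i - 1, j] + gap_open + gap_extend
                i -= 1
                if stop:
                    break
        elif h == E[i, j]:
            while True:
                columns += 1
                stop = E[i, j] == H[i, j - 1] + gap_open + gap_extend
                j -= 1
                if stop:
                    break
        else:  # pragma: no cover - defensive; cannot happen
            break
    return best, i, bi, j, bj, matches, columns


@njit(cache=True)
def scan_overlap(a, b, min_overlap, min_identity, off_lo, off_hi):
    """Best ungapped overlap of b placed at offsets [off_lo, off_hi] on a.

    Offset o means b[0] sits at coordinate o of a; dovetail and
    containment placements are both covered.  Only placements with at
    least min_overlap columns and identity >= min_identity qualify; the
    best maximises identity*length (= match count), then length, then
    the smallest offset.

    Returns (found, offset, length, matches); found is 0 when no
    placement qualifies.
    """
    la = a.shape[0]
    lb = b.shape[0]
    lo = max(off_lo, min_overlap - lb)
    hi = min(off_hi, la - min_overlap)
    best_match = -1
    best_len = 0
    best_off = 0
    found = 0
    for o in range(lo, hi + 1):
        start = o if o > 0 else 0
        end = o + lb if o + lb < la else la
        length = end - start
        if length < min_overlap:
            continue
        matches = 0
        for t in range(start, end):
            if a[t] == b[t - o]:
                matches += 1
        if matches < min_identity * length:
            continue
        if matches > best_match or (matches == best_match
                                    and length > best_len):
            best_match = matches
            best_len = length
            best_off = o
            found = 1
    return found, best_off, best_len, best_match


@njit(cache=True)
def scan_one_vs_many(new_codes, new_anchor, codes_list, anchors, idx,
                     min_overlap, min_identity, band, anchored):
    """Banded scan_overlap of one sequence against many (batched).

    Evaluates codes_list[i] as 'a' and new_codes as 'b' for each i in
    idx; returns per-candidate (found, offset, length, matches) arrays.
    """
    n = idx.shape[0]
    found = np.zeros(n, dtype=np.int8)
    offs = np.zeros(n, dtype=np.int64)
    lens = np.zeros(n, dtype=np.int64)
    matches = np.zeros(n, dtype=np.int64)
    for t in range(n):
        i = idx[t]
        a = codes_list[i]
        if anchored:
            d = new_anchor - anchors[i]
            lo, hi = d - band, d + band
            if hi < min_overlap - new_codes.shape[0] or \
                    lo > a.shape[0] - min_overlap:
                continue
        else:
            lo, hi = -(10**9), 10**9
        f, o, ln, m = scan_overlap(a, new_codes, min_overlap, min_identity,
                                   lo, hi)
        found[t] = f
        offs[t] = o
        lens[t] = ln
        matches[t] = m
    return found, offs, lens, matches


@njit(cache=True)
def kmer_codes(codes, k, base):
    """Rolling k-mer integer codes; k-mers containing code >= base get -1."""
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        v = np.int64(0)
        ok = True
        for t in range(k):
            c = codes[i + t]
            if c >= base:
                ok = False
                break
            v = v * base + c
        out[i] = v if ok else np.int64(-1)
    return out


@njit(cache=True)
def any_member(values, sorted_ref):
    """True if any non-negative value occurs in the sorted reference array."""
    n = sorted_ref.shape[0]
    for v in values:
        if v < 0:
            continue
        lo = 0
        hi = n
        while lo < hi:
            mid = (lo + hi) // 2
            if sorted_ref[mid] < v:
                lo = mid + 1
            else:
                hi = mid
        if lo < n and sorted_ref[lo] == v:
            return True
    return False
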