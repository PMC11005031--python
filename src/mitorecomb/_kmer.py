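"""Shared k-mer encoding and anchor-chaining primitives.

Both the repeat finder and the read aligner are built on exact k-mer matches
("anchors") found by integer-encoding k-mers (2 bits/base, k <= 31) and
locating equal codes.  Chaining groups anchors by diagonal (ref - query
offset) and keeps the densest collinear run, which is the standard long-read
seed-and-chain scheme at toy scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _v in zip(b"ACGT", range(4)):
    _BASE_CODE[_b] = _v
MAX_K = 31  # 2 bits/base in an int64, sign bit reserved for the N sentinel


def encode_bases(seq: str) -> np.ndarray:
    """uint8 base codes A,C,G,T -> 0..3; anything else (N) -> 255."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(base_codes: np.ndarray, k: int) -> np.ndarray:
    """int64 code per k-mer start position; windows containing N get -1."""
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = base_codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    c = base_codes.astype(np.int64)
    val = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for t in range(k):
        win = c[t : t + n]
        val = (val << 2) | (win & 3)
        bad |= win == 255
    val[bad] = -1
    return val


def revcomp_kmer_codes(base_codes: np.ndarray, k: int) -> np.ndarray:
    """Code of the reverse complement of each forward k-mer (same positions)."""
    n = base_codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    c = np.where(base_codes == 255, 255, 3 - base_codes.astype(np.int64))
    val = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for t in range(k - 1, -1, -1):
        win = c[t : t + n]
        val = (val << 2) | (win & 3)
        bad |= win == 255
    val[bad] = -1
    return val


@dataclass
class Chain:
    """Best collinear anchor chain of a read against one reference."""

    q_start: int
    q_end: int  # half-open, in query coordinates
    r_start: int
    r_end: int
    n_anchors: int
    aligned_bases: int  # query bases covered by chained anchors
    filled_bases: int  # as aligned_bases, but short anchor gaps count as aligned


class KmerIndex:
    """Exact k-mer index over a set of named reference strings.

    Lookup is fully vectorised: reference k-mer codes are sorted once and
    queries are resolved with searchsorted + CSR-style expansion.
    """

    def __init__(self, references: dict[str, str], k: int = 15):
        self.k = k
        self.names = list(references)
        codes_all = []
        rid_all = []
        pos_all = []
        for rid, name in enumerate(self.names):
            codes = kmer_codes(encode_bases(references[name]), k)
            keep = codes >= 0
            codes_all.append(codes[keep])
            pos_all.append(np.flatnonzero(keep).astype(np.int64))
            rid_all.append(np.full(keep.sum(), rid, dtype=np.int32))
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._rid = np.concatenate(rid_all)[order] if rid_all else np.empty(0, np.int32)
        self._pos = np.concatenate(pos_all)[order] if pos_all else np.empty(0, np.int64)
        # group boundaries for each distinct code
        if self._codes.size:
            is_start = np.empty(self._codes.size, dtype=bool)
            is_start[0] = True
            is_start[1:] = self._codes[1:] != self._codes[:-1]
            starts = np.flatnonzero(is_start)
            self._ucodes = self._codes[starts]
            self._off = np.append(starts, self._codes.size)
        else:
            self._ucodes = np.empty(0, np.int64)
            self._off = np.zeros(1, np.int64)

    def anchors(self, query_codes: np.ndarray, qpos: np.ndarray):
        """All (query_pos, ref_id, ref_pos) exact matches for the given k-mers."""
        valid = query_codes >= 0
        q = query_codes[valid]
        qp = qpos[valid]
        if q.size == 0 or self._ucodes.size == 0:
            e = np.empty(0, np.int64)
            return e, np.empty(0, np.int32), e
        idx = np.searchsorted(self._ucodes, q)
        idx_c = np.minimum(idx, self._ucodes.size - 1)
        hit = self._ucodes[idx_c] == q
        idx_h = idx_c[hit]
        starts = self._off[idx_h]
        counts = self._off[idx_h + 1] - starts
        total = int(counts.sum())
        if total == 0:
            e = np.empty(0, np.int64)
            return e, np.empty(0, np.int32), e
        out_q = np.repeat(qp[hit], counts)
        base = np.repeat(starts, counts)
        within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        take = base + within
        return out_q, self._rid[take], self._pos[take]


def covered_query_bases(qpos: np.ndarray, k: int) -> int:
    """Total query bases covered by length-k anchors at (sorted or not) qpos."""
    if qpos.size == 0:
        return 0
    qs = np.unique(qpos)
    if qs.size == 1:
        return k
    d = np.diff(qs)
    return int(np.minimum(d, k).sum() + k)


def covered_query_bases_filled(qpos: np.ndarray, k: int, gap_fill: int) -> int:
    """Query bases covered by anchors, counting short inter-anchor gaps
    (error-induced seed losses, <= gap_fill bp) as covered; long gaps are
    genuinely unaligned stretches and are not filled."""
    if qpos.size == 0:
        return 0
    qs = np.unique(qpos)
    if qs.size == 1:
        return k
    d = np.diff(qs)
    per_gap = np.where(d <= gap_fill, d, np.minimum(d, k))
    return int(per_gap.sum() + k)


def best_chain(
    qpos: np.ndarray, rpos: np.ndarray, k: int, band: int = 300, gap_fill: int = 200
) -> Chain | None:
    """Densest collinear chain among anchors of one (reference, strand).

    Anchors are clustered by diagonal (rpos - qpos) within ``band``; within
    the winning cluster, anchors are made monotone in reference position by a
    greedy running-max filter.  Score is query bases covered by kept anchors.
    """
    if qpos.size == 0:
        return None
    diag = rpos - qpos
    order = np.argsort(diag, kind="stable")
    d_sorted = diag[order]
    # two-pointer window over sorted diagonals maximizing anchor count
    left = np.searchsorted(d_sorted, d_sorted - band, side="left")
    counts = np.arange(d_sorted.size) - left + 1
    best_i = int(np.argmax(counts))
    lo, hi = left[best_i], best_i + 1
    sel = order[lo:hi]
    q = qpos[sel]
    r = rpos[sel]
    qorder = np.argsort(q, kind="stable")
    q = q[qorder]
    r = r[qorder]
    run_max = np.maximum.accumulate(r)
    keep = r >= run_max  # drop reference back-steps
    q = q[keep]
    r = r[keep]
    return Chain(
        q_start=int(q[0]),
        q_end=int(q[-1]) + k,
        r_start=int(r[0]),
        r_end=int(r[-1]) + k,
        n_anchors=int(q.size),
        aligned_bases=covered_query_bases(q, k),
        filled_bases=covered_query_bases_filled(q, k, gap_fill),
    )


def query_kmer_positions(n_kmers: int, stride: int) -> np.ndarray:
    """Strided query k-mer start positions, always including the final one."""
    if n_kmers <= 0:
        return np.empty(0, dtype=np.int64)
    pos = np.arange(0, n_kmers, stride, dtype=np.int64)
    if pos[-1] != n_kmers - 1:
        pos = np.append(pos, n_kmers - 1)
    return pos
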