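"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's seed-and-extend machinery: maximal
repeated pairs are found by scanning every diagonal of the (doubled)
sequence against itself and against its reverse complement, taking match
run-lengths, and re-extending each candidate with a definitional while-loop
on the tripled sequence.
"""

from __future__ import annotations

import numpy as np

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "?"}


def _revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def _extend_pair(seq: str, i: int, j: int, length: int, cls: str) -> tuple[int, int, int]:
    """Definitional maximal extension of a matching segment pair (mod-free,
    on the tripled string); returns (new_i, new_j, new_length)."""
    L = len(seq)
    t = seq * 3
    p, q = i + L, j + L
    if cls == "DR":
        while length < L and t[p - 1] == t[q - 1] != "N":
            p -= 1
            q -= 1
            length += 1
        while length < L and t[p + length] == t[q + length] != "N":
            length += 1
        return p - L, q - L, length
    # IR: seq[p:p+len] == revcomp(seq[q:q+len])
    while length < L and t[p + length] != "N" and t[p + length] == COMP[t[q - 1]]:
        q -= 1
        length += 1
    while length < L and t[p - 1] != "N" and t[p - 1] == COMP[t[q + length]]:
        p -= 1
        length += 1
    return p - L, q - L, length


def _normalize(L: int, i: int, j: int, length: int, cls: str) -> tuple | None:
    i %= L
    j %= L
    if i == j:
        return None
    if i > j:
        i, j = j, i
    return (i, i + length, j, j + length, cls)


def brute_force_maximal_pairs(seq: str, min_len: int) -> set[tuple]:
    """All maximal repeated segment pairs on the circle, as
    (start_a, end_a, start_b, end_b, class) tuples with start_a < start_b."""
    L = len(seq)
    d = seq + seq
    a = np.frombuffer(d.encode(), dtype=np.uint8)
    rc = np.frombuffer(_revcomp(d).encode(), dtype=np.uint8)
    found: set[tuple] = set()

    def runs(eq: np.ndarray):
        """(start, length) of maximal True runs."""
        if not eq.any():
            return
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            yield int(s), int(e - s)

    n2 = 2 * L
    # direct repeats: every forward diagonal shift
    for shift in range(1, n2):
        m = n2 - shift
        if m < min_len:
            break
        eq = a[:m] == a[shift:]
        for s, run in runs(eq):
            if run < min_len:
                continue
            i, j, length = _extend_pair(seq, s % L, (s + shift) % L, min(run, L), "DR")
            if length < min_len:
                continue
            key = _normalize(L, i, j, length, "DR")
            if key and (key[2] - key[0]) % L != 0:
                found.add(key)
    # inverted repeats: forward vs reverse complement.  rc[u] corresponds to
    # genome position (n2 - 1 - u); a match run a[x:x+l] == rc[y:y+l] means
    # seq[x:x+l] == revcomp(seq[n2-y-l : n2-y]).
    for off in range(-(n2 - 1), n2):
        lo_a = max(0, off)
        lo_r = max(0, -off)
        m = n2 - abs(off)
        if m < min_len:
            continue
        eq = a[lo_a : lo_a + m] == rc[lo_r : lo_r + m]
        for s, run in runs(eq):
            run = min(run, L)
            x = lo_a + s
            y = lo_r + s
            j_lin = n2 - y - run
            i, j, length = _extend_pair(seq, x % L, j_lin % L, run, "IR")
            if length < min_len:
                continue
            key = _normalize(L, i, j, length, "IR")
            if key:
                found.add(key)
    return found


def implementation_pairs_as_keys(pairs) -> set[tuple]:
    """MaximalPair list -> the oracle's normalized tuple representation."""
    out = set()
    for p in pairs:
        out.add(
            (
                p.copy_a.start,
                p.copy_a.end,
                p.copy_b.start,
                p.copy_b.end,
                p.pair_class,
            )
        )
    return out
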