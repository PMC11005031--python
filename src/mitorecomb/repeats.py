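"""Dispersed repeat discovery on circular genomes.

Detects maximal repeated segment pairs (direct and inverted) of a circular
molecule, groups them into repeat families, classifies copy pairs as DR/IR,
and resolves nesting relations (a short repeat wholly contained in a longer
one, which creates additional recombination substrates whose junction
evidence is partly shadowed by the outer family).

The finder is exact by default (``min_identity=1.0``): identical copies are
what drive clean homologous recombination.  A mild relaxation extends seeds
through isolated mismatches (no indels) while the running identity stays at
or above the threshold.

Algorithm: k-mer seeds on the doubled sequence (so wrapped copies are seen),
canonical seed codes covering both strands, diagonal run collapse, maximal
greedy extension in the tripled sequence, modular de-duplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from ._kmer import encode_bases, kmer_codes, revcomp_kmer_codes
from .genome import CircularSequence, Interval, reverse_complement

log = logging.getLogger(__name__)

MIN_SEED_LEN = 20  # seeds shorter than this are unreliable on ~100-kb molecules


@dataclass(frozen=True)
class MaximalPair:
    """One maximal repeated segment pair; copy_a starts before copy_b."""

    copy_a: Interval
    copy_b: Interval
    length: int
    pair_class: str  # "DR" or "IR"

    def key(self) -> tuple:
        return (
            self.copy_a.start,
            self.copy_a.end,
            self.copy_b.start,
            self.copy_b.end,
            self.pair_class,
        )


@dataclass
class RepeatCopy:
    label: str  # a, b, c, ... by ascending genome position
    interval: Interval


@dataclass
class RepeatFamily:
    family_id: int  # 1 = longest
    length: int
    copies: list[RepeatCopy]
    seq: str  # representative sequence (orientation of copy a, which is '+')

    def copy(self, label: str) -> RepeatCopy:
        for c in self.copies:
            if c.label == label:
                return c
        raise KeyError(f"family {self.family_id} has no copy {label!r}")


@dataclass(frozen=True)
class RepeatPair:
    family_id: int
    label_a: str
    label_b: str
    copy_a: Interval
    copy_b: Interval
    pair_class: str  # DR or IR
    length: int
    shadowed: bool = False

    @property
    def name(self) -> str:
        return f"Repeat-{self.family_id}{self.label_a}_{self.label_b}"


@dataclass(frozen=True)
class NestingRelation:
    inner_family: int
    inner_label: str
    outer_family: int
    outer_label: str
    offset_in_outer: Interval  # 0-based half-open within the outer copy's motif

    def offset_1based(self) -> tuple[int, int]:
        return self.offset_in_outer.start + 1, self.offset_in_outer.end


@dataclass
class RepeatCatalog:
    genome: CircularSequence
    families: list[RepeatFamily] = field(default_factory=list)

    @property
    def genome_length(self) -> int:
        return self.genome.length

    def family(self, family_id: int) -> RepeatFamily:
        for f in self.families:
            if f.family_id == family_id:
                return f
        raise KeyError(f"no repeat family {family_id}")

    def all_pairs(self) -> list[RepeatPair]:
        out: list[RepeatPair] = []
        for f in self.families:
            out.extend(pairs_for_family(self, f.family_id))
        return out

    def copies_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.families:
            for c in f.copies:
                s1, e1 = c.interval.to_1based(self.genome_length)
                rows.append(
                    {
                        "family_id": f.family_id,
                        "copy_label": c.label,
                        "start": s1,
                        "end": e1,
                        "strand": c.interval.strand,
                        "length": f.length,
                    }
                )
        return pd.DataFrame(
            rows, columns=["family_id", "copy_label", "start", "end", "strand", "length"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.copies_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# maximal repeated pair discovery


def _candidate_seed_pairs(seq: str, L: int, k: int):
    """Yield collapsed seed-pair representatives (p0, q0, pair_class).

    Works on the doubled sequence so wrapped copies produce in-range seeds.
    Canonical k-mer codes (min of forward and reverse-complement encoding)
    let one sort cover both DR and IR seed matches.
    """
    doubled = seq + seq
    bases = encode_bases(doubled)
    fwd = kmer_codes(bases, k)
    rev = revcomp_kmer_codes(bases, k)
    canon = np.minimum(fwd, rev)
    flag = fwd <= rev  # True when the forward encoding is the canonical one
    valid = (fwd >= 0) & (rev >= 0)
    pos = np.flatnonzero(valid)
    canon_v = canon[pos]
    order = np.argsort(canon_v, kind="stable")
    pos_s = pos[order]
    canon_s = canon_v[order]
    flag_s = flag[pos_s]

    # group boundaries
    starts = np.flatnonzero(np.concatenate(([True], canon_s[1:] != canon_s[:-1])))
    ends = np.append(starts[1:], canon_s.size)

    raw: list[tuple[int, int, str]] = []
    for s, e in zip(starts, ends):
        if e - s < 2:
            continue
        grp_pos = pos_s[s:e]
        grp_flag = flag_s[s:e]
        for i, j in combinations(range(e - s), 2):
            p, q = int(grp_pos[i]), int(grp_pos[j])
            same = bool(grp_flag[i]) == bool(grp_flag[j])
            p0, q0 = p % L, q % L
            if same:
                if p0 == q0:
                    continue
                if p0 > q0:
                    p0, q0 = q0, p0
                raw.append((p0, q0, "DR"))
            else:
                if p0 == q0:
                    continue  # self-palindrome, one physical copy
                if p0 > q0:
                    p0, q0 = q0, p0
                raw.append((p0, q0, "IR"))
    if not raw:
        return []
    raw = sorted(set(raw), key=lambda t: (t[2], (t[1] - t[0]) if t[2] == "DR" else (t[0] + t[1]), t[0]))
    reps: list[tuple[int, int, str]] = []
    prev_key = None
    prev_p = None
    for p0, q0, cls in raw:
        key = (cls, q0 - p0) if cls == "DR" else (cls, p0 + q0)
        if key != prev_key or p0 != prev_p + 1:
            reps.append((p0, q0, cls))
        prev_key = key
        prev_p = p0
    return reps


def _extend_exact(tripled: str, L: int, p: int, q: int, k: int, cls: str) -> tuple[int, int, int]:
    """Maximal exact extension of a seed; returns (left_ext, right_ext, length)."""
    lt = rt = 0
    n = len(tripled)
    if cls == "DR":
        while (
            k + lt + rt < L
            and p - 1 - lt >= 0
            and q - 1 - lt >= 0
            and tripled[p - 1 - lt] == tripled[q - 1 - lt] != "N"
        ):
            lt += 1
        while (
            k + lt + rt < L
            and p + k + rt < n
            and q + k + rt < n
            and tripled[p + k + rt] == tripled[q + k + rt] != "N"
        ):
            rt += 1
    else:  # IR: right extension of copy A pairs with left extension of copy B
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "?"}
        while (
            k + lt + rt < L
            and p + k + rt < n
            and q - 1 - rt >= 0
            and tripled[p + k + rt] != "N"
            and tripled[p + k + rt] == comp[tripled[q - 1 - rt]]
        ):
            rt += 1
        while (
            k + lt + rt < L
            and p - 1 - lt >= 0
            and q + k + lt < n
            and tripled[p - 1 - lt] != "N"
            and tripled[p - 1 - lt] == comp[tripled[q + k + lt]]
        ):
            lt += 1
    return lt, rt, k + lt + rt


def _extend_identity(
    tripled: str, L: int, p: int, q: int, k: int, cls: str, min_identity: float
) -> tuple[int, int, int]:
    """Greedy extension tolerating mismatches while identity stays >= threshold.

    No indels; the reported segment always ends on matching bases.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "?"}
    n = len(tripled)

    def pair_at(lt: int, rt: int, side: str) -> tuple[str, str]:
        if cls == "DR":
            if side == "L":
                return tripled[p - 1 - lt], tripled[q - 1 - lt]
            return tripled[p + k + rt], tripled[q + k + rt]
        if side == "L":
            return tripled[p - 1 - lt], comp[tripled[q + k + lt]]
        return tripled[p + k + rt], comp[tripled[q - 1 - rt]]

    def in_range(lt: int, rt: int, side: str) -> bool:
        if cls == "DR":
            if side == "L":
                return p - 1 - lt >= 0 and q - 1 - lt >= 0
            return p + k + rt < n and q + k + rt < n
        if side == "L":
            return p - 1 - lt >= 0 and q + k + lt < n
        return p + k + rt < n and q - 1 - rt >= 0

    lt = rt = 0
    matches = k
    for side in ("R", "L"):
        trail = 0  # candidate extension currently ending in mismatches
        while True:
            cur_lt, cur_rt = (lt, rt + trail) if side == "R" else (lt + trail, rt)
            if k + cur_lt + cur_rt >= L or not in_range(cur_lt, cur_rt, side):
                break
            x, y = pair_at(cur_lt, cur_rt, side)
            if "N" in (x, y) or "?" in (x, y):
                break
            new_len = k + cur_lt + cur_rt + 1
            new_matches = matches + (1 if x == y else 0)
            if x == y:
                # commit the pending stretch
                if side == "R":
                    rt = cur_rt + 1
                else:
                    lt = cur_lt + 1
                matches = new_matches
                trail = 0
            else:
                if new_matches / new_len < min_identity:
                    break
                matches = new_matches
                trail += 1
    return lt, rt, k + lt + rt


def maximal_repeat_pairs(
    genome: CircularSequence, min_len: int = 50, min_identity: float = 1.0
) -> list[MaximalPair]:
    """All maximal repeated segment pairs of length >= min_len on the circle."""
    if min_len < MIN_SEED_LEN:
        raise ValueError(f"min_len below {MIN_SEED_LEN} bp is refused (seed reliability)")
    L = genome.length
    if L < 2 * min_len:
        raise ValueError(f"genome of {L} bp is shorter than 2*min_len={2 * min_len}")
    if not 0.0 < min_identity <= 1.0:
        raise ValueError(f"min_identity must be in (0, 1], got {min_identity}")
    k = min(min_len, 25)
    seq = genome.seq
    tripled = seq * 3
    seen: set[tuple] = set()
    out: list[MaximalPair] = []
    for p0, q0, cls in _candidate_seed_pairs(seq, L, k):
        p = p0 + L
        q = q0 + L
        if min_identity >= 1.0:
            lt, rt, length = _extend_exact(tripled, L, p, q, k, cls)
        else:
            lt, rt, length = _extend_identity(tripled, L, p, q, k, cls, min_identity)
        if length < min_len:
            continue
        if cls == "DR":
            a = Interval((p0 - lt) % L, (p0 - lt) % L + length, "+")
            b = Interval((q0 - lt) % L, (q0 - lt) % L + length, "+")
        else:
            a = Interval((p0 - lt) % L, (p0 - lt) % L + length, "+")
            b = Interval((q0 - rt) % L, (q0 - rt) % L + length, "-")
        if a.start > b.start:
            a, b = Interval(b.start, b.end, "+"), Interval(a.start, a.end, "-" if cls == "IR" else "+")
        if (a.start, a.end) == (b.start, b.end):
            continue  # one physical copy (palindrome)
        pair = MaximalPair(a, b, length, cls)
        if pair.key() in seen:
            continue
        seen.add(pair.key())
        out.append(pair)
    out.sort(key=lambda m: (-m.length, m.copy_a.start, m.copy_b.start))
    return out


# ---------------------------------------------------------------------------
# family assembly


def _merge_copy_id(
    registry: list[Interval], iv: Interval, L: int, min_reciprocal: float = 0.9
) -> int:
    """Index of ``iv`` in the copy registry, merging near-identical intervals."""
    for i, known in enumerate(registry):
        if (known.start, known.end) == (iv.start, iv.end):
            return i
    for i, known in enumerate(registry):
        ov = known.overlap_length(iv, L)
        if ov >= min_reciprocal * known.length and ov >= min_reciprocal * iv.length:
            return i
    registry.append(Interval(iv.start, iv.end, "+"))
    return len(registry) - 1


def find_dispersed_repeats(
    genome: CircularSequence, min_len: int = 50, min_identity: float = 1.0
) -> RepeatCatalog:
    """Detect dispersed repeat families on a circular genome.

    Families are numbered 1..n by descending length (ties by first copy
    position); copies are lettered a, b, c, ... by ascending genome position,
    with copy a fixed on the '+' strand.
    """
    pairs = maximal_repeat_pairs(genome, min_len=min_len, min_identity=min_identity)
    L = genome.length

    registry: list[Interval] = []
    edges: list[tuple[int, int, str]] = []
    for mp in pairs:
        ia = _merge_copy_id(registry, mp.copy_a, L)
        ib = _merge_copy_id(registry, mp.copy_b, L)
        edges.append((ia, ib, mp.pair_class))

    # connected components with strand propagation (DR: same, IR: opposite)
    parent = list(range(len(registry)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ia, ib, _ in edges:
        parent[find(ia)] = find(ib)

    comp_members: dict[int, list[int]] = {}
    for i in range(len(registry)):
        comp_members.setdefault(find(i), []).append(i)

    adjacency: dict[int, list[tuple[int, str]]] = {i: [] for i in range(len(registry))}
    for ia, ib, cls in edges:
        adjacency[ia].append((ib, cls))
        adjacency[ib].append((ia, cls))

    families: list[RepeatFamily] = []
    for members in comp_members.values():
        if len(members) < 2:
            continue
        strand: dict[int, str] = {}
        root = members[0]
        strand[root] = "+"
        stack = [root]
        while stack:
            u = stack.pop()
            for v, cls in adjacency[u]:
                want = strand[u] if cls == "DR" else ("-" if strand[u] == "+" else "+")
                if v not in strand:
                    strand[v] = want
                    stack.append(v)
                elif strand[v] != want:
                    log.warning("inconsistent strand assignment within a repeat family")
        copies = sorted(members, key=lambda i: registry[i].start)
        if strand[copies[0]] == "-":
            strand = {i: ("-" if s == "+" else "+") for i, s in strand.items()}
        length = max(registry[i].length for i in copies)
        first = registry[copies[0]]
        rep_seq = genome.extract(Interval(first.start, first.end, "+"))
        fam_copies = [
            RepeatCopy(
                label=chr(ord("a") + n),
                interval=Interval(registry[i].start, registry[i].end, strand[i]),
            )
            for n, i in enumerate(copies)
        ]
        families.append(RepeatFamily(0, length, fam_copies, rep_seq))

    families.sort(key=lambda f: (-f.length, f.copies[0].interval.start))
    for fid, fam in enumerate(families, start=1):
        fam.family_id = fid
    return RepeatCatalog(genome=genome, families=families)


# ---------------------------------------------------------------------------
# nesting and pair listing


def _containment_shift(outer: Interval, inner: Interval, L: int) -> int | None:
    a = outer.normalized(L)
    b = inner.normalized(L)
    for shift in (-L, 0, L):
        if a.start <= b.start + shift and b.end + shift <= a.end:
            return shift
    return None


def detect_nesting(catalog: RepeatCatalog) -> list[NestingRelation]:
    """All containments of a shorter family's copy inside a longer family's copy."""
    L = catalog.genome_length
    out: list[NestingRelation] = []
    for outer_f in catalog.families:
        for inner_f in catalog.families:
            if inner_f.length >= outer_f.length:
                continue
            for oc in outer_f.copies:
                for ic in inner_f.copies:
                    shift = _containment_shift(oc.interval, ic.interval, L)
                    if shift is None:
                        continue
                    o = oc.interval.normalized(L)
                    i = ic.interval.normalized(L)
                    if oc.interval.strand == "+":
                        off = (i.start + shift) - o.start
                    else:
                        off = o.end - (i.end + shift)
                    rel_strand = "+" if ic.interval.strand == oc.interval.strand else "-"
                    out.append(
                        NestingRelation(
                            inner_family=inner_f.family_id,
                            inner_label=ic.label,
                            outer_family=outer_f.family_id,
                            outer_label=oc.label,
                            offset_in_outer=Interval(off, off + inner_f.length, rel_strand),
                        )
                    )
    return out


def pairs_for_family(catalog: RepeatCatalog, family_id: int) -> list[RepeatPair]:
    """Copy pairs of a family, with shadowing flags.

    A pair is *shadowed* when both copies are nested inside copies of one
    larger family: every read spanning such a junction also spans the outer
    family's junction, so the pair has no junction evidence of its own.
    """
    fam = catalog.family(family_id)
    L = catalog.genome_length
    nesting = [n for n in detect_nesting(catalog) if n.inner_family == family_id]
    outer_by_label: dict[str, set[int]] = {}
    for n in nesting:
        outer_by_label.setdefault(n.inner_label, set()).add(n.outer_family)
    out: list[RepeatPair] = []
    for ca, cb in combinations(fam.copies, 2):
        cls = "DR" if ca.interval.strand == cb.interval.strand else "IR"
        shadowed = bool(
            outer_by_label.get(ca.label, set()) & outer_by_label.get(cb.label, set())
        )
        out.append(
            RepeatPair(
                family_id=family_id,
                label_a=ca.label,
                label_b=cb.label,
                copy_a=ca.interval,
                copy_b=cb.interval,
                pair_class=cls,
                length=fam.length,
                shadowed=shadowed,
            )
        )
    return out


def nesting_frame(catalog: RepeatCatalog) -> pd.DataFrame:
    rows = []
    for n in detect_nesting(catalog):
        s1, e1 = n.offset_1based()
        rows.append(
            {
                "inner_family": n.inner_family,
                "inner_copy": n.inner_label,
                "outer_family": n.outer_family,
                "outer_copy": n.outer_label,
                "offset_start": s1,
                "offset_end": e1,
                "inner_length": n.offset_in_outer.length,
                "relative_strand": n.offset_in_outer.strand,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "inner_family",
            "inner_copy",
            "outer_family",
            "outer_copy",
            "offset_start",
            "offset_end",
            "inner_length",
            "relative_strand",
        ],
    )
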