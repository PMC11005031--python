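"""Junction references and read-support classification.

For each repeat pair, four reference sequences are assembled from 3,000-bp
flanks (U = upstream, D = downstream, after orienting both copies to present
the repeat R on the '+' strand):

    ref_a  = Ua + R + Da        ref_b  = Ub + R + Db      (assembly order)
    alt_ab = Ua + R + Db        alt_ba = Ub + R + Da      (recombinant order)

A long read supports a configuration when its primary alignment to this
four-sequence set covers at least 1,800 bp of the upstream flank AND at
least 1,800 bp of the downstream flank.  The 1,800-bp rule guarantees the
read anchors in sequence unique to the junction even when the repeat is
nested inside a longer one.  Per-pair support counts become the familiar
two-column percentage table (reference vs alternative rate).

The default alignment engine is an in-package k-mer anchor + collinear
chaining aligner; any object with the same ``align_batch`` contract (for
example the bundled minimap2 command-line adapter) can be substituted.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
import warnings
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from ._kmer import KmerIndex, best_chain, encode_bases, kmer_codes, query_kmer_positions
from .genome import CircularSequence, Interval, reverse_complement
from .repeats import RepeatPair

log = logging.getLogger(__name__)

JUNCTION_LABELS = ("ref_a", "ref_b", "alt_ab", "alt_ba")


@dataclass
class JunctionSet:
    """The four flank+repeat+flank references for one repeat pair."""

    pair: RepeatPair
    flank_len: int
    refs: dict[str, str]  # label -> sequence, labels as in JUNCTION_LABELS

    @property
    def repeat_length(self) -> int:
        return self.pair.length

    def reference_length(self) -> int:
        return 2 * self.flank_len + self.repeat_length


@dataclass
class ReadAlignment:
    """Primary (best single collinear) alignment of one read."""

    read_id: str
    reference: str | None
    strand: str
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    aligned_bases: int
    is_primary: bool = True
    filled_bases: int = 0  # aligned_bases with short in-chain gaps counted

    @property
    def aligned(self) -> bool:
        return self.reference is not None


def build_junctions(
    genome: CircularSequence, pair: RepeatPair, flank_len: int = 3000
) -> JunctionSet:
    """Assemble the four junction references for one repeat pair."""
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    L = genome.length
    if 2 * flank_len + pair.length > L:
        raise ValueError(
            f"2*flank_len + repeat length ({2 * flank_len + pair.length}) exceeds "
            f"genome length ({L})"
        )

    def context(iv: Interval) -> tuple[str, str, str]:
        """(upstream flank, repeat, downstream flank) in the copy's orientation."""
        s = iv.normalized(L)
        up = genome.extract(Interval((s.start - flank_len) % L, (s.start - flank_len) % L + flank_len, "+"))
        rep = genome.extract(Interval(s.start, s.end, "+"))
        down = genome.extract(Interval(s.end % L, s.end % L + flank_len, "+"))
        if iv.strand == "-":
            up, rep, down = (
                reverse_complement(down),
                reverse_complement(rep),
                reverse_complement(up),
            )
        return up, rep, down

    for this, other in ((pair.copy_a, pair.copy_b), (pair.copy_b, pair.copy_a)):
        s = this.normalized(L)
        flank_region = Interval(
            (s.start - flank_len) % L, (s.start - flank_len) % L + 2 * flank_len + s.length, "+"
        )
        if flank_region.contains(other, L):
            raise ValueError(
                f"{pair.name}: partner copy lies entirely within the flank region; "
                "junction references would be degenerate"
            )
        if flank_region.overlap_length(other, L) > 0:
            warnings.warn(
                f"{pair.name}: flank overlaps the partner copy; junction evidence "
                "may be ambiguous",
                stacklevel=2,
            )

    ua, ra, da = context(pair.copy_a)
    ub, rb, db = context(pair.copy_b)
    if ra != rb:
        raise ValueError(f"{pair.name}: copy sequences differ; junctions require identical copies")
    refs = {
        "ref_a": ua + ra + da,
        "ref_b": ub + ra + db,
        "alt_ab": ua + ra + db,
        "alt_ba": ub + ra + da,
    }
    return JunctionSet(pair=pair, flank_len=flank_len, refs=refs)


# ---------------------------------------------------------------------------
# alignment engines


class Aligner(Protocol):
    def align_batch(self, reads: Sequence[tuple[str, str]]) -> list[ReadAlignment]: ...


class KmerChainAligner:
    """k-mer anchor + collinear chaining aligner over a set of references.

    Returns, per read, the best-scoring single collinear local alignment
    (the primary) over all references and both strands; score is the number
    of query bases covered by chained anchors.  Ties break by reference
    order as given, then '+' strand.  Reliable for reads within ~5%
    divergence of a reference.
    """

    def __init__(self, references: dict[str, str], k: int = 15, stride: int = 5, band: int = 300):
        self.references = dict(references)
        self.k = k
        self.stride = stride
        self.band = band
        self._index = KmerIndex(self.references, k=k)
        self._order = {name: i for i, name in enumerate(self._index.names)}

    def align(
        self, read_id: str, seq: str, strands: tuple[str, ...] = ("+", "-")
    ) -> ReadAlignment:
        best: ReadAlignment | None = None
        best_rank: tuple | None = None
        for strand in strands:
            oriented = seq if strand == "+" else reverse_complement(seq)
            codes = kmer_codes(encode_bases(oriented), self.k)
            qsel = query_kmer_positions(codes.size, self.stride)
            qp, rid, rp = self._index.anchors(codes[qsel], qsel)
            for r in np.unique(rid):
                mask = rid == r
                chain = best_chain(qp[mask], rp[mask], self.k, band=self.band)
                if chain is None:
                    continue
                name = self._index.names[int(r)]
                rank = (-chain.aligned_bases, self._order[name], 0 if strand == "+" else 1)
                if best_rank is None or rank < best_rank:
                    best_rank = rank
                    n = len(seq)
                    if strand == "+":
                        q_start, q_end = chain.q_start, chain.q_end
                    else:  # report query span on the original read orientation
                        q_start, q_end = n - chain.q_end, n - chain.q_start
                    best = ReadAlignment(
                        read_id=read_id,
                        reference=name,
                        strand=strand,
                        query_start=q_start,
                        query_end=q_end,
                        ref_start=chain.r_start,
                        ref_end=chain.r_end,
                        aligned_bases=chain.aligned_bases,
                        filled_bases=chain.filled_bases,
                    )
        if best is None:
            return ReadAlignment(read_id, None, "+", 0, 0, 0, 0, 0, is_primary=False)
        return best

    def align_batch(self, reads: Sequence[tuple[str, str]]) -> list[ReadAlignment]:
        return [self.align(rid, seq) for rid, seq in reads]

    def per_reference_query_coverage(self, seq: str) -> dict[str, float]:
        """Fraction of query bases covered by anchors, per reference (both
        strands pooled; no chaining).  Used by the read-curation filters."""
        from ._kmer import covered_query_bases

        n = len(seq)
        cov: dict[str, set] = {}
        acc: dict[int, list[np.ndarray]] = {}
        for strand in ("+", "-"):
            oriented = seq if strand == "+" else reverse_complement(seq)
            codes = kmer_codes(encode_bases(oriented), self.k)
            qsel = query_kmer_positions(codes.size, self.stride)
            qp, rid, _ = self._index.anchors(codes[qsel], qsel)
            if strand == "-":
                qp = (n - self.k) - qp
            for r in np.unique(rid):
                acc.setdefault(int(r), []).append(qp[rid == r])
        out = {}
        for r, chunks in acc.items():
            qs = np.concatenate(chunks)
            out[self._index.names[r]] = covered_query_bases(qs, self.k) / n
        return out


class Minimap2Aligner:
    """Adapter satisfying the same primary-alignment contract via the
    minimap2 executable (PAF output).  Used as an independent cross-check."""

    def __init__(self, references: dict[str, str], preset: str = "map-hifi",
                 executable: str = "minimap2"):
        if shutil.which(executable) is None:
            raise RuntimeError(f"{executable!r} not found on PATH")
        self.references = dict(references)
        self.preset = preset
        self.executable = executable
        self._order = {name: i for i, name in enumerate(references)}

    def align_batch(self, reads: Sequence[tuple[str, str]]) -> list[ReadAlignment]:
        with tempfile.TemporaryDirectory() as tmp:
            ref_fa = Path(tmp) / "refs.fa"
            reads_fa = Path(tmp) / "reads.fa"
            ref_fa.write_text("".join(f">{n}\n{s}\n" for n, s in self.references.items()))
            reads_fa.write_text("".join(f">{rid}\n{s}\n" for rid, s in reads))
            res = subprocess.run(
                [self.executable, "-x", self.preset, "-c", "--secondary=no",
                 str(ref_fa), str(reads_fa)],
                capture_output=True, text=True, check=True,
            )
        best: dict[str, ReadAlignment] = {}
        rank: dict[str, tuple] = {}
        for line in res.stdout.splitlines():
            f = line.split("\t")
            rid, qs, qe, strand = f[0], int(f[2]), int(f[3]), f[4]
            ref, rs, re_, nmatch = f[5], int(f[7]), int(f[8]), int(f[9])
            r = (-nmatch, self._order[ref], 0 if strand == "+" else 1)
            if rid not in rank or r < rank[rid]:
                rank[rid] = r
                best[rid] = ReadAlignment(
                    rid, ref, strand, qs, qe, rs, re_, nmatch, filled_bases=nmatch
                )
        return [
            best.get(rid, ReadAlignment(rid, None, "+", 0, 0, 0, 0, 0, is_primary=False))
            for rid, _ in reads
        ]


def align_read(read_id: str, seq: str, references: dict[str, str], **kwargs) -> ReadAlignment:
    """One-off convenience wrapper around :class:`KmerChainAligner`."""
    return KmerChainAligner(references, **kwargs).align(read_id, seq)


# ---------------------------------------------------------------------------
# classification and rates


def classify_read(
    aln: ReadAlignment, jset: JunctionSet, min_flank_overlap: int = 1800
) -> str:
    """Label a primary alignment, or 'unassigned' if the dual-flank rule fails.

    The alignment's reference span must cover >= min_flank_overlap bases of
    the upstream flank AND of the downstream flank.
    """
    if min_flank_overlap > jset.flank_len:
        raise ValueError(
            f"min_flank_overlap ({min_flank_overlap}) exceeds flank_len ({jset.flank_len})"
        )
    if not aln.aligned or aln.reference not in jset.refs:
        return "unassigned"
    f = jset.flank_len
    rep = jset.repeat_length
    upstream_covered = max(0, min(aln.ref_end, f) - aln.ref_start)
    downstream_covered = max(0, aln.ref_end - max(aln.ref_start, f + rep))
    if upstream_covered >= min_flank_overlap and downstream_covered >= min_flank_overlap:
        return aln.reference
    return "unassigned"


def count_support(
    reads: Iterable[tuple[str, str]],
    jset: JunctionSet,
    min_flank_overlap: int = 1800,
    aligner: Aligner | None = None,
    **aligner_kwargs,
) -> Counter:
    """Classify a read set against one junction set; returns label counts."""
    if aligner is None:
        aligner = KmerChainAligner(jset.refs, **aligner_kwargs)
    labels = Counter()
    for aln in aligner.align_batch(list(reads)):
        labels[classify_read(aln, jset, min_flank_overlap)] += 1
    return labels


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class PairCounts:
    name: str
    pair_class: str
    length: int
    n_reference: int
    n_alternative: int

    @classmethod
    def from_labels(cls, pair: RepeatPair, labels: Counter) -> "PairCounts":
        return cls(
            name=pair.name,
            pair_class=pair.pair_class,
            length=pair.length,
            n_reference=labels.get("ref_a", 0) + labels.get("ref_b", 0),
            n_alternative=labels.get("alt_ab", 0) + labels.get("alt_ba", 0),
        )


def support_rates(counts: Sequence[PairCounts]) -> pd.DataFrame:
    """Per-pair support table: counts and 2-decimal percentage rates.

    Percentages are count/(n_ref+n_alt)*100 rounded half-away-from-zero;
    rows with no assigned reads keep counts 0 and blank rates.
    """
    rows = []
    for c in counts:
        total = c.n_reference + c.n_alternative
        if total == 0:
            pct_ref = pct_alt = float("nan")
        else:
            pct_ref = _round2(100.0 * c.n_reference / total)
            pct_alt = _round2(100.0 * c.n_alternative / total)
        rows.append(
            {
                "pair": c.name,
                "class": c.pair_class,
                "length": c.length,
                "pct_reference": pct_ref,
                "n_reference": c.n_reference,
                "pct_alternative": pct_alt,
                "n_alternative": c.n_alternative,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair", "class", "length",
            "pct_reference", "n_reference",
            "pct_alternative", "n_alternative",
        ],
    )


def write_support_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.2f")
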