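"""Long-read curation: compartment extraction, duplex-artifact removal,
and full-length linear accounting against a reference and an alternative
genome form.

* Organelle read extraction keeps a read as mitochondrial only when its
  total query coverage against the mitogenome reference reaches 70%
  (coverage sums non-overlapping query spans over all alignments to that
  compartment, so split alignments accumulate).
* Duplex-like reads — sequencing artifacts whose two halves are reverse
  complements mapping to the same locus on opposite strands — are removed
  because they cannot align linearly.
* Full-length accounting asks, per read, whether a single collinear chain
  covers at least 95% of its bases on the reference form (checked first) or
  on an alternative form; references are doubled internally so reads
  crossing the circular origin still align linearly.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .genome import CircularSequence, reverse_complement
from .junctions import KmerChainAligner
from .recombine import GenomeForm

log = logging.getLogger(__name__)


@dataclass
class ReadRecord:
    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"read {self.id!r}: quality length differs from sequence length")

    @property
    def length(self) -> int:
        return len(self.seq)


def read_reads(path: str | Path) -> list[ReadRecord]:
    """Load FASTA or FASTQ reads; gzip auto-detected by .gz extension."""
    path = Path(path)
    fmt = "fastq" if ".fastq" in path.suffixes or ".fq" in path.suffixes else "fasta"
    opener = gzip.open if path.suffix == ".gz" else open
    out = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append(ReadRecord(rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    path = Path(path)
    payload = "".join(
        f"@{r.id}\n{r.seq}\n+\n{r.qual if r.qual is not None else 'I' * r.length}\n"
        for r in reads
    ).encode("ascii")
    if path.suffix == ".gz":
        # fixed mtime so identical simulations are byte-identical on disk
        with open(path, "wb") as raw, gzip.GzipFile(
            filename="", fileobj=raw, mode="wb", mtime=0
        ) as fh:
            fh.write(payload)
    else:
        path.write_bytes(payload)


@dataclass
class FullLengthReport:
    n_total: int
    n_mc1_full: int
    n_alt_full: int
    n_unexplained: int

    @property
    def fraction_explained(self) -> float:
        if self.n_total == 0:
            return float("nan")
        return (self.n_mc1_full + self.n_alt_full) / self.n_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_total": self.n_total,
                    "n_mc1_full": self.n_mc1_full,
                    "n_alt_full": self.n_alt_full,
                    "n_unexplained": self.n_unexplained,
                    "fraction_explained": self.fraction_explained,
                }
            ]
        )


def _doubled_refs(prefix: str, circles: Sequence[CircularSequence]) -> dict[str, str]:
    return {f"{prefix}_c{i + 1}": c.seq + c.seq for i, c in enumerate(circles)}


def _as_circles(form) -> list[CircularSequence]:
    if isinstance(form, CircularSequence):
        return [form]
    if isinstance(form, GenomeForm):
        return form.circles
    return list(form)


def extract_organelle_reads(
    reads: Sequence[ReadRecord],
    refs: dict[str, CircularSequence | str],
    min_query_coverage: float = 0.70,
    k: int = 15,
    stride: int = 10,
) -> dict[str, list[ReadRecord]]:
    """Partition reads by compartment of their best alignment.

    ``refs`` maps compartment names (must include 'mito') to reference
    sequences.  A read lands in the 'mito' bin only if its query coverage on
    the mitogenome reference is at least ``min_query_coverage``; reads whose
    best compartment is mito but fall below the threshold, or with no
    alignment at all, land in 'unassigned'.
    """
    if "mito" not in refs:
        raise ValueError("refs must include a 'mito' reference")
    ref_seqs = {}
    for name, r in refs.items():
        seq = r.seq if isinstance(r, CircularSequence) else str(r)
        ref_seqs[name] = seq + seq  # doubled: circular compartments align linearly
    aligner = KmerChainAligner(ref_seqs, k=k, stride=stride)
    bins: dict[str, list[ReadRecord]] = {name: [] for name in refs}
    bins["unassigned"] = []
    for read in reads:
        cov = aligner.per_reference_query_coverage(read.seq)
        if not cov:
            bins["unassigned"].append(read)
            continue
        best = max(cov, key=lambda n: (cov[n], n))
        if best == "mito" and cov[best] < min_query_coverage:
            bins["unassigned"].append(read)
        else:
            bins[best].append(read)
    return bins


def remove_duplex_like(
    reads: Sequence[ReadRecord],
    reference: CircularSequence | str,
    min_reciprocal_overlap: float = 0.80,
    k: int = 15,
    stride: int = 5,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Drop reads whose two halves align to the same region on opposite strands.

    Returns (kept, removed).  The reciprocal-overlap threshold between the
    two halves' reference spans defaults to 80%.
    """
    seq = reference.seq if isinstance(reference, CircularSequence) else str(reference)
    aligner = KmerChainAligner({"ref": seq + seq}, k=k, stride=stride)
    L = len(seq)

    def spans_match(a1, a2) -> bool:
        # the doubled reference carries two images of every locus; compare
        # spans modulo the original length
        if not (a1.aligned and a2.aligned):
            return False
        inter = 0
        for shift in (-L, 0, L):
            lo = max(a1.ref_start, a2.ref_start + shift)
            hi = min(a1.ref_end, a2.ref_end + shift)
            inter = max(inter, hi - lo)
        len1 = a1.ref_end - a1.ref_start
        len2 = a2.ref_end - a2.ref_start
        return bool(
            len1
            and len2
            and inter >= min_reciprocal_overlap * len1
            and inter >= min_reciprocal_overlap * len2
        )

    def opposite(strand: str) -> tuple[str, ...]:
        return ("-",) if strand == "+" else ("+",)

    kept, removed = [], []
    for read in reads:
        half = read.length // 2
        h1, h2 = read.seq[:half], read.seq[half:]
        a1 = aligner.align(read.id + "/1", h1)
        a2 = aligner.align(read.id + "/2", h2)
        duplex = a1.strand != a2.strand and spans_match(a1, a2)
        # a half lying inside an inverted-repeat copy multi-maps: test the
        # duplex hypothesis explicitly by pinning the partner half to the
        # opposite strand and asking for the same reference span
        if not duplex and a1.aligned:
            a2r = aligner.align(read.id + "/2", h2, strands=opposite(a1.strand))
            duplex = a2r.aligned_bases >= 0.3 * len(h2) and spans_match(a1, a2r)
        if not duplex and a2.aligned:
            a1r = aligner.align(read.id + "/1", h1, strands=opposite(a2.strand))
            duplex = a1r.aligned_bases >= 0.3 * len(h1) and spans_match(a1r, a2)
        (removed if duplex else kept).append(read)
    return kept, removed


def _full_length_on(aligner: KmerChainAligner, read: ReadRecord, threshold: float) -> bool:
    """Does one collinear chain align >= threshold of the read's bases on any
    reference?  Short in-chain anchor gaps (sequencing-error seed losses)
    count as aligned; long unaligned stretches do not."""
    best = aligner.align(read.id, read.seq)
    if not best.aligned:
        return False
    return best.filled_bases >= threshold * read.length


def full_length_accounting(
    reads: Sequence[ReadRecord],
    mc1,
    alt_form,
    threshold: float = 0.95,
    k: int = 15,
    stride: int = 5,
) -> FullLengthReport:
    """Classify reads as fully-linear on the reference form, on the
    alternative form, or unexplained.

    A read counts for the reference form MC1 when a single collinear chain
    (no strand switch, monotone coordinates) covers >= ``threshold`` of its
    bases there; the reference is tested first, then the alternative, so the
    counts partition the read set.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    mc1_aligner = KmerChainAligner(_doubled_refs("mc1", _as_circles(mc1)), k=k, stride=stride)
    alt_aligner = KmerChainAligner(_doubled_refs("alt", _as_circles(alt_form)), k=k, stride=stride)
    n_mc1 = n_alt = n_unexp = 0
    for read in reads:
        if _full_length_on(mc1_aligner, read, threshold):
            n_mc1 += 1
        elif _full_length_on(alt_aligner, read, threshold):
            n_alt += 1
        else:
            n_unexp += 1
    return FullLengthReport(
        n_total=len(reads), n_mc1_full=n_mc1, n_alt_full=n_alt, n_unexplained=n_unexp
    )
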