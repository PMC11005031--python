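"""Circular-sequence data model and FASTA I/O.

Plant mitochondria (and plastids) are conventionally represented as a single
circular "master circle" molecule.  Two linear strings describe the same
circular molecule whenever one is a rotation of the other, or a rotation of
its reverse complement.  This module provides the :class:`CircularSequence`
container, modular-coordinate extraction, a canonical form for molecule
equality, and FASTA round-tripping with a ``circular=true`` header tag.

Coordinates are 0-based half-open internally; report output is rendered
1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


@dataclass(frozen=True)
class Interval:
    """Half-open span on a circular molecule.

    ``end`` may exceed the molecule length to denote a span that wraps across
    the origin.  ``strand`` is '+' or '-'; extraction on '-' returns the
    reverse complement.
    """

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"interval end must exceed start: [{self.start}, {self.end})")
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_1based(self, molecule_length: int | None = None) -> tuple[int, int]:
        """(start, end) as 1-based inclusive; wrapped ends are reduced mod length."""
        start1 = self.start + 1
        end1 = self.end
        if molecule_length is not None:
            start1 = (self.start % molecule_length) + 1
            end1 = ((self.end - 1) % molecule_length) + 1
        return start1, end1

    def normalized(self, molecule_length: int) -> "Interval":
        """Shift start into [0, molecule_length); length preserved."""
        s = self.start % molecule_length
        return Interval(s, s + self.length, self.strand)

    def contains(self, other: "Interval", molecule_length: int) -> bool:
        """Modular containment: does this span fully contain ``other``?"""
        a = self.normalized(molecule_length)
        b = other.normalized(molecule_length)
        for shift in (-molecule_length, 0, molecule_length):
            if a.start <= b.start + shift and b.end + shift <= a.end:
                return True
        return False

    def overlap_length(self, other: "Interval", molecule_length: int) -> int:
        """Modular overlap in bp between the two spans."""
        a = self.normalized(molecule_length)
        b = other.normalized(molecule_length)
        best = 0
        for shift in (-molecule_length, 0, molecule_length):
            lo = max(a.start, b.start + shift)
            hi = min(a.end, b.end + shift)
            best = max(best, hi - lo)
        return best


@dataclass
class CircularSequence:
    """A circular DNA molecule stored linearly with an arbitrary origin."""

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def extract(self, iv: Interval) -> str:
        """Subsequence for ``iv``, wrapping across the origin when needed."""
        if iv.length > self.length:
            raise ValueError(
                f"requested span of {iv.length} bp exceeds molecule length {self.length}"
            )
        s = iv.start % self.length
        doubled = self.seq + self.seq
        out = doubled[s : s + iv.length]
        return reverse_complement(out) if iv.strand == "-" else out

    def rotate(self, k: int) -> "CircularSequence":
        """Same molecule with the origin moved to position ``k``."""
        k %= self.length
        return replace(self, seq=self.seq[k:] + self.seq[:k])

    def canonical_form(self) -> str:
        return canonical_form(self)

    def __eq__(self, other: object) -> bool:  # identity of the labelled record
        if not isinstance(other, CircularSequence):
            return NotImplemented
        return self.id == other.id and self.seq == other.seq


def _least_rotation(s: str) -> str:
    """Lexicographically minimal rotation (Booth's algorithm, O(n))."""
    s2 = s + s
    n2 = len(s2)
    f = [-1] * n2
    k = 0
    for j in range(1, n2):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return s2[k : k + len(s)]


def canonical_form(c: CircularSequence | str) -> str:
    """Canonical representative of a circular molecule.

    The lexicographically minimal string over all rotations of the sequence
    and all rotations of its reverse complement.  Two circular molecules are
    the same iff their canonical forms are equal.
    """
    seq = c.seq if isinstance(c, CircularSequence) else c
    return min(_least_rotation(seq), _least_rotation(reverse_complement(seq)))


def extract(c: CircularSequence, iv: Interval) -> str:
    """Functional alias for :meth:`CircularSequence.extract`."""
    return c.extract(iv)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> list[CircularSequence]:
    """Read a multi-FASTA into CircularSequence records.

    Lowercase input is uppercased (logged).  Circularity is taken from a
    ``circular=true`` / ``circular=false`` tag in the description; records
    without a tag default to circular (this package's primary subject).
    Illegal characters raise with the offending record named.
    """
    out: list[CircularSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        seq = raw.upper()
        if seq != raw:
            log.info("record %s: lowercase bases uppercased on read", rec.id)
        circular = "circular=false" not in rec.description.lower()
        try:
            out.append(CircularSequence(rec.id, seq, circular=circular))
        except ValueError as exc:
            raise ValueError(f"malformed FASTA record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(
    seqs: Iterable[CircularSequence],
    path: str | Path,
    wrap: int = 80,
) -> None:
    """Write records with a circularity header tag; wrap at 60 or 80 columns."""
    if wrap not in (60, 80):
        raise ValueError(f"line wrap must be 60 or 80, got {wrap}")
    records = []
    for c in seqs:
        rec = SeqRecord(Seq(c.seq), id=c.id, description=f"circular={str(c.circular).lower()}")
        records.append(rec)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)
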