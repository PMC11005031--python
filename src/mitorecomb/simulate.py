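"""Planted-truth synthetic genomes and isomer-mixture long-read simulation.

The generator emulates the structure this analysis assumes: a circular
genome of order 10^5 bp carrying a large inverted-repeat pair (~9 kb), a
large direct-repeat pair (~1.5 kb) with a short repeat nested inside it plus
a free-standing third copy, and several smaller dispersed pairs; and long
reads (10-20 kb typical) drawn from a stated mixture of isomeric genome
forms with configurable i.i.d. substitution/insertion/deletion errors.

Everything is deterministic given the seed (byte-identical output), and the
generator returns the ground-truth repeat catalog so the finder can be
tested against planted truth.  Copy boundaries are forced to be maximal:
after stamping, the base flanking each copy is adjusted so no repeat pair
extends by chance beyond its planted length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import CircularSequence, Interval, reverse_complement
from .recombine import GenomeForm
from .readfilter import ReadRecord
from .repeats import RepeatCatalog, RepeatCopy, RepeatFamily

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {65: 84, 67: 71, 71: 67, 84: 65}  # A<->T, C<->G on byte codes


@dataclass
class RepeatSpec:
    """One planted repeat family.

    ``placements`` are (position, strand) stampings of the family motif on
    the background.  ``nested_inside=(outer_index, offset)`` derives the
    motif from a slice of an earlier spec's motif, so the family implicitly
    gains one copy inside every placement of the outer family; its own
    ``placements`` then list only the free-standing copies.
    """

    length: int
    placements: list[tuple[int, str]]
    nested_inside: tuple[int, int] | None = None


@dataclass
class MixtureSpec:
    """Mixture of genome forms reads are drawn from; proportions sum to 1."""

    proportions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions sum to {total}, expected 1")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("mixture proportions must be non-negative")


@dataclass
class ReadSimSpec:
    """Read simulation parameters (HiFi-like defaults).

    Lengths are lognormal with the given mean (bp), truncated to
    [min_len, max_len]; error rates are i.i.d. per base and must lie in
    [0, 0.1].  The seed is mandatory for reproducibility.
    """

    n_reads: int
    seed: int
    mean_len: float = 15000.0
    sigma: float = 0.25
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    min_len: int = 1000
    max_len: int = 50000

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 0.1:
                raise ValueError(f"{name} must be in [0, 0.1], got {r}")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


ONT_LIKE = dict(mean_len=25000.0, sigma=0.35, sub_rate=0.02, ins_rate=0.01, del_rate=0.01)


def paper_like_repeats() -> list[RepeatSpec]:
    """The default planted geometry: a 9-kb IR pair, a 1,467-bp DR pair with
    a 188-bp repeat nested at motif positions 1,173-1,360 plus a free third
    copy in inverted orientation, and three smaller pairs (564/317/161 bp)."""
    return [
        RepeatSpec(9000, [(5_000, "+"), (35_000, "-")]),                 # family 1 (IR)
        RepeatSpec(1467, [(55_000, "+"), (75_000, "+")]),                # family 2 (DR)
        RepeatSpec(564, [(16_000, "+"), (28_000, "-")]),                 # family 3 (IR)
        RepeatSpec(317, [(47_000, "+"), (51_500, "-")]),                 # family 4 (IR)
        RepeatSpec(188, [(90_000, "-")], nested_inside=(1, 1172)),       # family 5 (nested)
        RepeatSpec(161, [(60_000, "+"), (80_000, "+")]),                 # family 6 (DR)
    ]


PAPER_LIKE_TOTAL_LEN = 100_000


def _derived_copies(spec: RepeatSpec, specs: list[RepeatSpec]) -> list[tuple[int, str]]:
    """All copies of a spec: nested-derived placements plus explicit ones."""
    out = list(spec.placements)
    if spec.nested_inside is not None:
        oi, off = spec.nested_inside
        outer = specs[oi]
        for opos, ostrand in outer.placements:
            if ostrand == "+":
                out.append((opos + off, "+"))
            else:
                out.append((opos + outer.length - off - spec.length, "-"))
    return sorted(out)


def make_genome(
    total_len: int,
    repeat_specs: list[RepeatSpec],
    seed: int,
    gc: float = 0.5,
    genome_id: str = "synthetic_mc1",
) -> tuple[CircularSequence, RepeatCatalog]:
    """Uniform-background circular genome with repeats written in at the
    specified placements; returns the molecule and the ground-truth catalog.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=total_len, p=p)

    # motifs (nested motifs are slices of their outer motif)
    motifs: list[np.ndarray] = []
    for i, spec in enumerate(repeat_specs):
        if spec.nested_inside is not None:
            oi, off = spec.nested_inside
            if oi >= i:
                raise ValueError("nested_inside must reference an earlier spec")
            if off + spec.length > repeat_specs[oi].length:
                raise ValueError(
                    f"nested offset {off} + length {spec.length} exceeds outer length "
                    f"{repeat_specs[oi].length}"
                )
            motifs.append(motifs[oi][off : off + spec.length].copy())
        else:
            motifs.append(rng.choice(_BASES, size=spec.length, p=p))

    # feasibility: explicit stampings must not overlap each other
    stamped: list[tuple[int, int, int]] = []  # (start, end, spec index)
    for i, spec in enumerate(repeat_specs):
        for pos, strand in spec.placements:
            s, e = pos % total_len, pos % total_len + spec.length
            if e > total_len:
                raise ValueError(
                    f"placement of spec {i} at {pos} wraps the origin; place it elsewhere"
                )
            for s2, e2, j in stamped:
                if s < e2 and s2 < e:
                    raise ValueError(
                        f"placement conflict: spec {i} at [{s},{e}) overlaps spec {j} at [{s2},{e2})"
                    )
            stamped.append((s, e, i))

    for i, spec in enumerate(repeat_specs):
        motif = motifs[i]
        for pos, strand in spec.placements:
            copy = motif if strand == "+" else _revcomp_arr(motif)
            arr[pos : pos + spec.length] = copy

    immutable = np.zeros(total_len, dtype=bool)
    for s, e, _ in stamped:
        immutable[s:e] = True

    _enforce_maximality(arr, immutable, repeat_specs, rng)

    genome = CircularSequence(genome_id, arr.tobytes().decode("ascii"))
    catalog = _truth_catalog(genome, repeat_specs)
    return genome, catalog


def _revcomp_arr(motif: np.ndarray) -> np.ndarray:
    out = np.empty_like(motif)
    for b, c in _COMP.items():
        out[motif[::-1] == b] = c
    return out


def _enforce_maximality(
    arr: np.ndarray, immutable: np.ndarray, specs: list[RepeatSpec], rng: np.random.Generator
) -> None:
    """Adjust copy-flanking background bases so planted repeats are maximal.

    For each family and each side, the motif-oriented flanking base of every
    copy is made distinct across copies (mutating only background bases;
    flanks that lie inside another planted copy — the nested case — are left
    alone, which is exactly the intended shadowing).
    """
    total = arr.size
    for i, spec in enumerate(specs):
        copies = _derived_copies(spec, specs)
        for side in ("before", "after"):
            slots = []  # (genome position or None, complemented?, current char)
            for pos, strand in copies:
                if (side == "before") == (strand == "+"):
                    gpos = (pos - 1) % total
                else:
                    gpos = (pos + spec.length) % total
                comp = strand == "-"
                base = int(arr[gpos])
                oriented = _COMP[base] if comp else base
                slots.append((gpos, comp, oriented))
            used: set[int] = set()
            for gpos, comp, oriented in slots:
                if immutable[gpos]:
                    used.add(oriented)
            for gpos, comp, oriented in slots:
                if immutable[gpos]:
                    continue
                if oriented in used:
                    choices = [b for b in (65, 67, 71, 84) if b not in used]
                    if not choices:
                        continue  # >4 copies on one side; vanishingly unlikely here
                    oriented = int(rng.choice(choices))
                    arr[gpos] = _COMP[oriented] if comp else oriented
                used.add(oriented)


def _truth_catalog(genome: CircularSequence, specs: list[RepeatSpec]) -> RepeatCatalog:
    entries = []
    for i, spec in enumerate(specs):
        copies = _derived_copies(spec, specs)
        ivs = [Interval(pos, pos + spec.length, strand) for pos, strand in copies]
        if ivs[0].strand == "-":
            ivs = [
                Interval(iv.start, iv.end, "+" if iv.strand == "-" else "-") for iv in ivs
            ]
        entries.append((spec.length, ivs))
    entries.sort(key=lambda t: (-t[0], t[1][0].start))
    families = []
    for fid, (length, ivs) in enumerate(entries, start=1):
        rep = genome.extract(Interval(ivs[0].start, ivs[0].end, "+"))
        families.append(
            RepeatFamily(
                family_id=fid,
                length=length,
                copies=[RepeatCopy(chr(ord("a") + n), iv) for n, iv in enumerate(ivs)],
                seq=rep,
            )
        )
    return RepeatCatalog(genome=genome, families=families)


# ---------------------------------------------------------------------------
# read simulation


def _apply_errors(codes: np.ndarray, sim: ReadSimSpec, rng: np.random.Generator) -> np.ndarray:
    if sim.sub_rate == sim.ins_rate == sim.del_rate == 0:
        return codes
    n = codes.size
    u = rng.random(n)
    ps, pd_, pi = sim.sub_rate, sim.del_rate, sim.ins_rate
    sub = u < ps
    dele = (u >= ps) & (u < ps + pd_)
    ins = (u >= ps + pd_) & (u < ps + pd_ + pi)
    out = codes.copy()
    if sub.any():
        # substitute with one of the three other bases
        idx = {65: 0, 67: 1, 71: 2, 84: 3}
        vals = np.array([65, 67, 71, 84], dtype=np.uint8)
        cur = np.searchsorted(vals, out[sub])
        shift = rng.integers(1, 4, size=int(sub.sum()))
        out[sub] = vals[(cur + shift) % 4]
    reps = np.ones(n, dtype=np.int64)
    reps[dele] = 0
    reps[ins] = 2
    expanded = np.repeat(out, reps)
    if ins.any():
        # the duplicated slot becomes a random inserted base
        ins_targets = np.cumsum(reps)[ins] - 1
        expanded[ins_targets] = rng.choice(_BASES, size=int(ins.sum()))
    return expanded


def simulate_reads(
    forms: dict[str, GenomeForm],
    mixture: MixtureSpec,
    sim: ReadSimSpec,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Draw reads from a mixture of genome forms.

    Per read: the form is chosen by mixture proportion, the circle within
    the form proportionally to circle length, the start uniformly on the
    circle, the length lognormally (truncated to the circle length), the
    strand uniformly; errors are applied per the spec.  Returns the reads
    and a truth table (read_id, form, circle, start, strand, true_len).
    """
    missing = set(mixture.proportions) - set(forms)
    if missing:
        raise ValueError(f"mixture names absent from forms: {sorted(missing)}")
    rng = np.random.default_rng(sim.seed)
    names = sorted(mixture.proportions)
    probs = np.array([mixture.proportions[n] for n in names])
    mu = np.log(sim.mean_len) - sim.sigma**2 / 2

    reads: list[ReadRecord] = []
    rows = []
    form_draws = rng.choice(len(names), size=sim.n_reads, p=probs)
    for i in range(sim.n_reads):
        form = forms[names[form_draws[i]]]
        lens = np.array([c.length for c in form.circles], dtype=float)
        ci = int(rng.choice(len(lens), p=lens / lens.sum()))
        circle = form.circles[ci]
        true_len = int(np.clip(rng.lognormal(mu, sim.sigma), sim.min_len, sim.max_len))
        true_len = min(true_len, circle.length)
        start = int(rng.integers(0, circle.length))
        doubled = circle.seq + circle.seq
        frag = doubled[start : start + true_len]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = reverse_complement(frag)
        codes = np.frombuffer(frag.encode("ascii"), dtype=np.uint8)
        codes = _apply_errors(codes, sim, rng)
        read_id = f"sim_{i:06d}"
        reads.append(ReadRecord(read_id, codes.tobytes().decode("ascii")))
        rows.append(
            {
                "read_id": read_id,
                "form": form.name,
                "circle": circle.id,
                "start": start,
                "strand": strand,
                "true_len": true_len,
            }
        )
    truth = pd.DataFrame(rows, columns=["read_id", "form", "circle", "start", "strand", "true_len"])
    return reads, truth


def make_duplex_artifacts(
    reads: list[ReadRecord], fraction: float, seed: int
) -> tuple[list[ReadRecord], list[bool]]:
    """Replace a fraction of reads with seg+revcomp(seg) duplex-like chimeras.

    Returns the modified read list and per-read truth flags (True = artifact).
    """
    if not 0.0 <= fraction <= 0.5:
        raise ValueError(f"fraction must be in [0, 0.5], got {fraction}")
    rng = np.random.default_rng(seed)
    n_art = int(round(fraction * len(reads)))
    chosen = set(rng.choice(len(reads), size=n_art, replace=False)) if n_art else set()
    out = []
    flags = []
    for i, r in enumerate(reads):
        if i in chosen:
            seg = r.seq[: r.length // 2]
            out.append(ReadRecord(r.id + "_duplex", seg + reverse_complement(seg)))
            flags.append(True)
        else:
            out.append(r)
            flags.append(False)
    return out, flags
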