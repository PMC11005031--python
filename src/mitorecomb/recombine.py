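"""Homologous-recombination algebra on circular molecules.

Intramolecular recombination between two identical repeat copies has two
outcomes depending on their relative orientation:

* an **inverted repeat (IR)** pair mediates a reversible *flip-flop*
  inversion of the segment between the copies, toggling between two master
  circle isomers (MC1 and MC2);
* a **direct repeat (DR)** pair mediates *fission* of the circle into two
  subcircles (each carrying one repeat copy), and the reverse *fusion*
  restores a single circle — the multipartite "two-circle model".

Because the copies are identical, every crossover point inside the repeat
yields the same product, so products are defined at repeat-copy granularity.
:func:`enumerate_forms` closes a founding master circle under a set of
active repeat pairs, de-duplicating products by the canonical forms of their
circles, and names forms with the field's superscript convention
(MC1, MC2, MC1^2, MC2^2, MC2^5ac, ...).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from itertools import combinations

from .genome import CircularSequence, Interval, canonical_form, reverse_complement
from .repeats import RepeatCatalog, RepeatPair

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecombinationEvent:
    family_id: int
    labels: tuple[str, str]
    kind: str  # inversion | fission | fusion

    def suffix(self, n_family_copies: int) -> str:
        if n_family_copies > 2:
            return f"{self.family_id}{self.labels[0]}{self.labels[1]}"
        return str(self.family_id)


@dataclass
class GenomeForm:
    name: str
    circles: list[CircularSequence]
    provenance: list[RecombinationEvent] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.circles)

    @property
    def n_circles(self) -> int:
        return len(self.circles)

    def canonical_key(self) -> tuple[str, ...]:
        return tuple(sorted(canonical_form(c) for c in self.circles))

    def provenance_string(self) -> str:
        if not self.provenance:
            return "founding"
        return ";".join(f"{e.kind}@{e.family_id}{e.labels[0]}_{e.labels[1]}" for e in self.provenance)


def _ordered_copies(circle: CircularSequence, pair: RepeatPair) -> tuple[Interval, Interval, int]:
    """Copies of a pair as non-wrapping intervals on a common rotation.

    If either copy wraps the origin the circle is rotated internally (the
    caller-visible product differs only by rotation, which is immaterial for
    a circular molecule).  Returns (first, second, rotation_applied).
    """
    L = circle.length
    a = pair.copy_a.normalized(L)
    b = pair.copy_b.normalized(L)
    rot = 0
    if a.end > L or b.end > L:
        rot = a.start
        a = Interval((a.start - rot) % L, (a.start - rot) % L + a.length, a.strand)
        b = Interval((b.start - rot) % L, (b.start - rot) % L + b.length, b.strand)
        if b.end > L:
            raise ValueError("repeat copies overlap the origin irreconcilably")
    if a.start > b.start:
        a, b = b, a
    if a.end > b.start:
        raise ValueError(
            f"repeat copies overlap ([{a.start},{a.end}) vs [{b.start},{b.end})); "
            "recombination product is undefined"
        )
    return a, b, rot


def invert_at_ir(circle: CircularSequence, pair: RepeatPair) -> CircularSequence:
    """Flip-flop inversion: reverse-complement the arc strictly between the
    two IR copies (the arc not containing the origin, by convention)."""
    if pair.pair_class != "IR":
        raise ValueError(f"{pair.name} is a DR pair; inversion requires an IR pair")
    a, b, rot = _ordered_copies(circle, pair)
    seq = circle.seq if rot == 0 else circle.seq[rot:] + circle.seq[:rot]
    out = seq[: a.end] + reverse_complement(seq[a.end : b.start]) + seq[b.start :]
    return CircularSequence(f"{circle.id}|inv{pair.family_id}", out)


def split_at_dr(circle: CircularSequence, pair: RepeatPair) -> tuple[CircularSequence, CircularSequence]:
    """Fission at a DR pair: two subcircles, each with one full repeat copy."""
    if pair.pair_class != "DR":
        raise ValueError(f"{pair.name} is an IR pair; fission requires a DR pair")
    a, b, rot = _ordered_copies(circle, pair)
    seq = circle.seq if rot == 0 else circle.seq[rot:] + circle.seq[:rot]
    c1 = seq[a.start : b.start]  # copy a + arc to copy b
    c2 = seq[b.start :] + seq[: a.start]  # copy b + remaining arc
    return (
        CircularSequence(f"{circle.id}|fis{pair.family_id}a", c1),
        CircularSequence(f"{circle.id}|fis{pair.family_id}b", c2),
    )


def locate_family(circle: CircularSequence, family_seq: str) -> list[Interval]:
    """Exact occurrences of a repeat motif (either strand) on a circle.

    The doubled sequence is searched so occurrences wrapping the origin are
    found; duplicate mod-length hits are collapsed.
    """
    L = circle.length
    doubled = circle.seq + circle.seq
    found: dict[tuple[int, str], Interval] = {}
    for strand, motif in (("+", family_seq), ("-", reverse_complement(family_seq))):
        start = doubled.find(motif)
        while start != -1:
            s = start % L
            found.setdefault((s, strand), Interval(s, s + len(motif), strand))
            start = doubled.find(motif, start + 1)
    # a palindromic motif would be reported on both strands at one locus
    out = []
    seen_pos = set()
    for (s, _), iv in sorted(found.items()):
        if s in seen_pos:
            continue
        seen_pos.add(s)
        out.append(iv)
    return out


def fuse(circle_a: CircularSequence, circle_b: CircularSequence, family_seq: str) -> CircularSequence:
    """Fusion at a shared repeat: inverse of :func:`split_at_dr`.

    Each circle must carry exactly one copy of the family; a circle whose
    copy is on the '-' strand is reverse-complemented first so both copies
    present the repeat in the same orientation.
    """
    parts = []
    for circle in (circle_a, circle_b):
        hits = locate_family(circle, family_seq)
        if len(hits) != 1:
            raise ValueError(
                f"circle {circle.id!r} carries {len(hits)} copies of the fusion repeat "
                "(exactly one required)"
            )
        hit = hits[0]
        seq = circle.seq
        if hit.strand == "-":
            seq = reverse_complement(seq)
            s = circle.length - hit.end
        else:
            s = hit.start
        parts.append(seq[s:] + seq[:s])  # rotated so the repeat copy leads
    return CircularSequence(f"{circle_a.id}+{circle_b.id}", parts[0] + parts[1])


# ---------------------------------------------------------------------------
# closure / enumeration


def _toggle_base(name: str) -> str:
    if name.startswith("MC1"):
        return "MC2" + name[3:]
    if name.startswith("MC2"):
        return "MC1" + name[3:]
    raise ValueError(f"unexpected form name {name!r}")


def _pair_for_copies(fid: int, fam_len: int, ca, cb) -> RepeatPair:
    cls = "DR" if ca.interval.strand == cb.interval.strand else "IR"
    return RepeatPair(
        family_id=fid,
        label_a=ca.label,
        label_b=cb.label,
        copy_a=ca.interval,
        copy_b=cb.interval,
        pair_class=cls,
        length=fam_len,
    )


def enumerate_forms(
    master: CircularSequence,
    catalog: RepeatCatalog,
    active_pairs: list[RepeatPair],
    max_events: int = 2,
    max_forms: int = 256,
) -> list[GenomeForm]:
    """Breadth-first closure of recombination events from a master circle.

    ``active_pairs`` selects which family/letter-pair combinations may
    recombine.  Repeat copies are re-located in every product by exact motif
    search, so nested and moved copies are handled without coordinate
    bookkeeping.  Forms are de-duplicated by the multiset of canonical forms
    of their circles; the first-discovered name is kept, which collapses
    commuting event orders (e.g. MC2^2 and MC1^2-then-inversion).
    """
    if max_events < 0:
        raise ValueError("max_events must be >= 0")
    allowed: dict[int, set[tuple[str, str]]] = {}
    for p in active_pairs:
        allowed.setdefault(p.family_id, set()).add(tuple(sorted((p.label_a, p.label_b))))
    fam_seqs = {fid: catalog.family(fid).seq for fid in allowed}
    fam_lens = {fid: catalog.family(fid).length for fid in allowed}

    base = GenomeForm("MC1", [master], [])
    forms: dict[tuple[str, ...], GenomeForm] = {base.canonical_key(): base}
    frontier = deque([base])
    for _ in range(max_events):
        next_frontier: deque[GenomeForm] = deque()
        for form in frontier:
            for fid, letter_pairs in allowed.items():
                motif = fam_seqs[fid]
                located: list[tuple[int, object]] = []  # (circle index, RepeatCopy-like)
                for ci, circle in enumerate(form.circles):
                    for iv in locate_family(circle, motif):
                        located.append((ci, iv))
                located.sort(key=lambda t: (t[0], t[1].start))
                labelled = [
                    (ci, _Copy(chr(ord("a") + n), iv)) for n, (ci, iv) in enumerate(located)
                ]
                for (ci_a, ca), (ci_b, cb) in combinations(labelled, 2):
                    if tuple(sorted((ca.label, cb.label))) not in allowed[fid]:
                        continue
                    pair = _pair_for_copies(fid, fam_lens[fid], ca, cb)
                    products = _apply_event(form, ci_a, ci_b, pair, motif)
                    for new_circles, event in products:
                        candidate = GenomeForm(
                            _derive_name(form.name, event, n_copies=len(labelled)),
                            new_circles,
                            form.provenance + [event],
                        )
                        key = candidate.canonical_key()
                        if key in forms:
                            continue
                        if len(forms) >= max_forms:
                            raise RuntimeError(
                                f"recombination closure exceeded the form cap "
                                f"({max_forms} forms reached)"
                            )
                        forms[key] = candidate
                        next_frontier.append(candidate)
        frontier = next_frontier
    out = list(forms.values())
    for f in out:
        if f.total_length != master.length:
            raise AssertionError("recombination did not conserve total length")
    # distinct forms can in principle derive the same name along different
    # event paths; disambiguate so form names stay unique identifiers
    seen_names: dict[str, int] = {}
    for f in out:
        n = seen_names.get(f.name, 0)
        seen_names[f.name] = n + 1
        if n:
            f.name = f"{f.name}#{n + 1}"
    return out


@dataclass
class _Copy:
    label: str
    interval: Interval


def _apply_event(form: GenomeForm, ci_a: int, ci_b: int, pair: RepeatPair, motif: str):
    """Possible products of recombining two located copies in a form."""
    out = []
    if ci_a == ci_b:
        circle = form.circles[ci_a]
        others = [c for i, c in enumerate(form.circles) if i != ci_a]
        try:
            if pair.pair_class == "IR":
                product = invert_at_ir(circle, pair)
                event = RecombinationEvent(pair.family_id, (pair.label_a, pair.label_b), "inversion")
                out.append((others + [product], event))
            else:
                c1, c2 = split_at_dr(circle, pair)
                event = RecombinationEvent(pair.family_id, (pair.label_a, pair.label_b), "fission")
                out.append((others + [c1, c2], event))
        except ValueError:
            log.debug("skipping degenerate event at family %d", pair.family_id)
    else:
        ca, cb = form.circles[ci_a], form.circles[ci_b]
        # fusion only when each partner circle carries exactly one family copy
        if len(locate_family(ca, motif)) == 1 and len(locate_family(cb, motif)) == 1:
            others = [c for i, c in enumerate(form.circles) if i not in (ci_a, ci_b)]
            product = fuse(ca, cb, motif)
            event = RecombinationEvent(pair.family_id, (pair.label_a, pair.label_b), "fusion")
            out.append((others + [product], event))
    return out


def _derive_name(parent: str, event: RecombinationEvent, n_copies: int) -> str:
    if event.family_id == 1 and event.kind == "inversion":
        return _toggle_base(parent)
    return f"{parent}^{event.suffix(n_copies)}"


def forms_manifest(forms: list[GenomeForm]) -> "pd.DataFrame":
    import pandas as pd

    rows = [
        {
            "form": f.name,
            "n_circles": f.n_circles,
            "lengths": ",".join(str(c.length) for c in f.circles),
            "provenance": f.provenance_string(),
        }
        for f in forms
    ]
    return pd.DataFrame(rows, columns=["form", "n_circles", "lengths", "provenance"])
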