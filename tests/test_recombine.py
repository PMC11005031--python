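"""Recombination algebra: inversion, fission/fusion, closure enumeration."""

import numpy as np
import pytest

from mitorecomb.genome import CircularSequence, Interval, canonical_form, reverse_complement
from mitorecomb.recombine import (
    enumerate_forms,
    fuse,
    invert_at_ir,
    locate_family,
    split_at_dr,
)
from mitorecomb.repeats import RepeatPair, find_dispersed_repeats


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _ir_toy(rng, lens=(40, 30, 50, 60)):
    P, R, X, Q = (_rand(rng, n) for n in lens)
    seq = P + R + X + reverse_complement(R) + Q
    a = Interval(len(P), len(P) + len(R), "+")
    b = Interval(len(P) + len(R) + len(X), len(P) + len(R) + len(X) + len(R), "-")
    pair = RepeatPair(1, "a", "b", a, b, "IR", len(R))
    return CircularSequence("toy", seq), pair, (P, R, X, Q)


def _dr_toy(rng, lens=(40, 30, 50, 60)):
    P, R, X, Q = (_rand(rng, n) for n in lens)
    seq = P + R + X + R + Q
    a = Interval(len(P), len(P) + len(R), "+")
    b = Interval(len(P) + len(R) + len(X), len(P) + len(R) + len(X) + len(R), "+")
    pair = RepeatPair(1, "a", "b", a, b, "DR", len(R))
    return CircularSequence("toy", seq), pair, (P, R, X, Q)


class TestInversion:
    def test_definitional_product(self, rng):
        c, pair, (P, R, X, Q) = _ir_toy(rng)
        inv = invert_at_ir(c, pair)
        assert inv.seq == P + R + reverse_complement(X) + reverse_complement(R) + Q

    def test_involution_up_to_canonical_form(self, rng):
        for _ in range(50):
            c, pair, _ = _ir_toy(rng)
            twice = invert_at_ir(invert_at_ir(c, pair), pair)
            assert canonical_form(twice) == canonical_form(c)

    def test_complementary_arc_gives_same_molecule(self, rng):
        c, pair, (P, R, X, Q) = _ir_toy(rng)
        inv = invert_at_ir(c, pair)
        # inverting the other arc (through the origin) instead: revcomp of
        # Q+P between the repeat copies read the other way round
        other = reverse_complement(Q + P)
        alt = CircularSequence("alt", X + reverse_complement(R) + other + R)
        assert canonical_form(alt) == canonical_form(inv)

    def test_dr_pair_rejected(self, rng):
        c, pair, _ = _dr_toy(rng)
        with pytest.raises(ValueError, match="DR pair"):
            invert_at_ir(c, pair)

    def test_overlapping_copies_rejected(self, rng):
        seq = _rand(rng, 200)
        pair = RepeatPair(1, "a", "b", Interval(10, 60, "+"), Interval(40, 90, "-"), "IR", 50)
        with pytest.raises(ValueError, match="overlap"):
            invert_at_ir(CircularSequence("t", seq), pair)

    def test_base_composition_conserved(self, rng):
        c, pair, _ = _ir_toy(rng)
        inv = invert_at_ir(c, pair)

        def comp_pairs(s):
            return sorted(min(b, {"A": "T", "T": "A", "C": "G", "G": "C"}[b]) for b in s)

        assert comp_pairs(inv.seq) == comp_pairs(c.seq)


class TestFissionFusion:
    def test_definitional_split(self, rng):
        c, pair, (P, R, X, Q) = _dr_toy(rng)
        c1, c2 = split_at_dr(c, pair)
        assert c1.seq == R + X
        assert c2.seq == R + Q + P

    def test_length_conservation(self, rng):
        for _ in range(25):
            c, pair, _ = _dr_toy(rng)
            c1, c2 = split_at_dr(c, pair)
            assert c1.length + c2.length == c.length

    def test_split_fuse_roundtrip(self, rng):
        for _ in range(50):
            c, pair, (P, R, X, Q) = _dr_toy(rng)
            c1, c2 = split_at_dr(c, pair)
            fused = fuse(c1, c2, R)
            assert canonical_form(fused) == canonical_form(c)

    def test_fuse_single_base_toys_matches_hand_construction(self):
        # two circles sharing a one-copy repeat "AC": fusion interleaves them
        c1 = CircularSequence("c1", "ACGGG")
        c2 = CircularSequence("c2", "ACTTT")
        fused = fuse(c1, c2, "AC")
        assert canonical_form(fused) == canonical_form("ACGGGACTTT")

    def test_ir_pair_rejected(self, rng):
        c, pair, _ = _ir_toy(rng)
        with pytest.raises(ValueError, match="IR pair"):
            split_at_dr(c, pair)

    def test_fuse_requires_single_copy_each(self, rng):
        R = _rand(rng, 30)
        c1 = CircularSequence("c1", R + _rand(rng, 50) + R)  # two copies
        c2 = CircularSequence("c2", R + _rand(rng, 50))
        with pytest.raises(ValueError, match="copies"):
            fuse(c1, c2, R)


class TestLocateFamily:
    def test_finds_wrapped_and_minus_strand_copies(self, rng):
        motif = _rand(rng, 60)
        bg = _rand(rng, 500)
        seq = motif[30:] + bg[:200] + reverse_complement(motif) + bg[200:] + motif[:30]
        hits = locate_family(CircularSequence("t", seq), motif)
        assert len(hits) == 2
        strands = {h.strand for h in hits}
        assert strands == {"+", "-"}


class TestEnumeration:
    def test_no_active_pairs_is_base_form_only(self, paper_scene):
        forms = enumerate_forms(paper_scene.genome, paper_scene.catalog, [], max_events=2)
        assert [f.name for f in forms] == ["MC1"]

    def test_four_major_forms_from_ir_plus_dr(self, paper_scene):
        forms = enumerate_forms(
            paper_scene.genome, paper_scene.catalog, paper_scene.active, max_events=2
        )
        assert len(forms) == 4
        assert {f.name for f in forms} == {"MC1", "MC2", "MC1^2", "MC2^2"}
        two_circle = [f for f in forms if f.n_circles == 2]
        assert {f.name for f in two_circle} == {"MC1^2", "MC2^2"}

    def test_total_length_conserved(self, paper_scene):
        for f in paper_scene.forms.values():
            assert f.total_length == paper_scene.genome.length

    def test_repeat_content_preserved_in_products(self, paper_scene):
        mc2 = paper_scene.forms["MC2"]
        cat2 = find_dispersed_repeats(mc2.circles[0])
        lengths = sorted(f.length for f in cat2.families)
        truth_lengths = sorted(f.length for f in paper_scene.catalog.families)
        assert lengths == truth_lengths

    def test_closure_matches_exhaustive_event_sequences(self, rng):
        """BFS closure equals a DFS over all event sequences (independent
        bookkeeping: copies re-located per product, events applied directly)."""
        bg = _rand(rng, 3000)
        R1, R2, R3 = _rand(rng, 120), _rand(rng, 90), _rand(rng, 60)
        seq = (
            bg[:300] + R1 + bg[300:700] + reverse_complement(R1)
            + bg[700:1200] + R2 + bg[1200:1700] + R2
            + bg[1700:2200] + R3 + bg[2200:2600] + reverse_complement(R3) + bg[2600:]
        )
        genome = CircularSequence("toy", seq)
        catalog = find_dispersed_repeats(genome)
        active = catalog.all_pairs()
        forms = enumerate_forms(genome, catalog, active, max_events=2, max_forms=512)

        motifs = [catalog.family(p.family_id).seq for p in active]
        motifs = sorted(set(motifs), key=len, reverse=True)

        seen = set()

        def key(circles):
            return tuple(sorted(canonical_form(c) for c in circles))

        def events(circles):
            out = []
            for motif in motifs:
                located = []
                for ci, c in enumerate(circles):
                    for iv in locate_family(c, motif):
                        located.append((ci, iv))
                for x in range(len(located)):
                    for y in range(x + 1, len(located)):
                        (ca, iva), (cb, ivb) = located[x], located[y]
                        if ca == cb:
                            cls = "DR" if iva.strand == ivb.strand else "IR"
                            pair = RepeatPair(1, "a", "b", iva, ivb, cls, len(motif))
                            circle = circles[ca]
                            rest = [c for i, c in enumerate(circles) if i != ca]
                            if cls == "IR":
                                out.append(rest + [invert_at_ir(circle, pair)])
                            else:
                                out.append(rest + list(split_at_dr(circle, pair)))
                        else:
                            rest = [
                                c for i, c in enumerate(circles) if i not in (ca, cb)
                            ]
                            out.append(rest + [fuse(circles[ca], circles[cb], motif)])
            return out

        def dfs(circles, depth):
            seen.add(key(circles))
            if depth == 0:
                return
            for product in events(circles):
                dfs(product, depth - 1)

        dfs([genome], 2)
        assert {f.canonical_key() for f in forms} == seen

    def test_form_cap_raises(self, paper_scene):
        with pytest.raises(RuntimeError, match="form cap"):
            enumerate_forms(
                paper_scene.genome,
                paper_scene.catalog,
                paper_scene.active,
                max_events=2,
                max_forms=2,
            )

    def test_negative_max_events_rejected(self, paper_scene):
        with pytest.raises(ValueError):
            enumerate_forms(paper_scene.genome, paper_scene.catalog, [], max_events=-1)
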