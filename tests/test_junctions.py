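"""Junction references, read alignment/classification, support rates."""

import math

import numpy as np
import pytest

from mitorecomb.genome import CircularSequence, Interval, reverse_complement
from mitorecomb.junctions import (
    JunctionSet,
    KmerChainAligner,
    Minimap2Aligner,
    PairCounts,
    build_junctions,
    classify_read,
    count_support,
    support_rates,
)
from mitorecomb.recombine import invert_at_ir, split_at_dr
from mitorecomb.repeats import RepeatPair, find_dispersed_repeats


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


FLANK = 300
OVERLAP = 180


@pytest.fixture
def dr_scene(rng):
    P, R, X, Q = _rand(rng, 800), _rand(rng, 200), _rand(rng, 900), _rand(rng, 1100)
    genome = CircularSequence("g", P + R + X + R + Q)
    a = Interval(len(P), len(P) + len(R), "+")
    b = Interval(len(P) + len(R) + len(X), len(P) + len(R) + len(X) + len(R), "+")
    pair = RepeatPair(1, "a", "b", a, b, "DR", len(R))
    return genome, pair, (P, R, X, Q)


@pytest.fixture
def ir_scene(rng):
    P, R, X, Q = _rand(rng, 800), _rand(rng, 200), _rand(rng, 900), _rand(rng, 1100)
    genome = CircularSequence("g", P + R + X + reverse_complement(R) + Q)
    a = Interval(len(P), len(P) + len(R), "+")
    b = Interval(len(P) + len(R) + len(X), len(P) + len(R) + len(X) + len(R), "-")
    pair = RepeatPair(1, "a", "b", a, b, "IR", len(R))
    return genome, pair, (P, R, X, Q)


class TestBuildJunctions:
    def test_dr_references_are_definitional(self, dr_scene):
        genome, pair, (P, R, X, Q) = dr_scene
        jset = build_junctions(genome, pair, FLANK)
        assert jset.refs["ref_a"] == P[-FLANK:] + R + X[:FLANK]
        assert jset.refs["ref_b"] == X[-FLANK:] + R + Q[:FLANK]
        assert jset.refs["alt_ab"] == P[-FLANK:] + R + Q[:FLANK]
        assert jset.refs["alt_ba"] == X[-FLANK:] + R + X[:FLANK]
        assert all(len(s) == 2 * FLANK + len(R) for s in jset.refs.values())

    def test_ir_alt_flanks_are_revcomp_context(self, ir_scene):
        genome, pair, (P, R, X, Q) = ir_scene
        jset = build_junctions(genome, pair, FLANK)
        # copy b presents the repeat on '-' so its flanks are revcomp context
        ub = reverse_complement(Q[:FLANK])
        db = reverse_complement(X[-FLANK:])
        assert jset.refs["ref_b"] == ub + R + db
        assert jset.refs["alt_ab"] == P[-FLANK:] + R + db

    def test_inverted_genome_swaps_ref_and_alt(self, ir_scene):
        genome, _, _ = ir_scene
        # derive the maximal pair from the finder (a planted copy may extend
        # by a chance flanking base)
        (pair,) = find_dispersed_repeats(genome, min_len=150).all_pairs()
        jset = build_junctions(genome, pair, FLANK)
        product = invert_at_ir(genome, pair)
        (newpair,) = find_dispersed_repeats(product, min_len=150).all_pairs()
        assert newpair.length == pair.length
        jset2 = build_junctions(product, newpair, FLANK)
        assert jset2.refs["ref_a"] in (jset.refs["alt_ab"], jset.refs["alt_ba"])
        assert jset2.refs["alt_ab"] in (jset.refs["ref_a"], jset.refs["ref_b"])

    def test_fission_subcircles_carry_the_alt_junctions(self, dr_scene):
        from mitorecomb.genome import Interval
        from mitorecomb.recombine import locate_family

        genome, _, _ = dr_scene
        (pair,) = find_dispersed_repeats(genome, min_len=150).all_pairs()
        jset = build_junctions(genome, pair, FLANK)
        fam_seq = genome.extract(pair.copy_a)
        contexts = []
        for circle in split_at_dr(genome, pair):
            (hit,) = locate_family(circle, fam_seq)
            up = circle.extract(
                Interval((hit.start - FLANK) % circle.length,
                         (hit.start - FLANK) % circle.length + FLANK, "+")
            )
            down = circle.extract(
                Interval(hit.end % circle.length, hit.end % circle.length + FLANK, "+")
            )
            contexts.append(up + fam_seq + down)
        assert set(contexts) == {jset.refs["alt_ab"], jset.refs["alt_ba"]}

    def test_flank_containing_partner_copy_errors(self, rng):
        P, R, X = _rand(rng, 2000), _rand(rng, 100), _rand(rng, 150)
        genome = CircularSequence("g", P + R + X + R + _rand(rng, 2000))
        a = Interval(len(P), len(P) + 100, "+")
        b = Interval(len(P) + 250, len(P) + 350, "+")
        pair = RepeatPair(1, "a", "b", a, b, "DR", 100)
        with pytest.raises(ValueError, match="within the flank"):
            build_junctions(genome, pair, 500)

    def test_flank_overlapping_partner_copy_warns(self, rng):
        P, R, X = _rand(rng, 2000), _rand(rng, 300), _rand(rng, 200)
        genome = CircularSequence("g", P + R + X + R + _rand(rng, 2000))
        a = Interval(len(P), len(P) + 300, "+")
        b = Interval(len(P) + 500, len(P) + 800, "+")
        pair = RepeatPair(1, "a", "b", a, b, "DR", 300)
        with pytest.warns(UserWarning, match="ambiguous"):
            build_junctions(genome, pair, 400)

    def test_genome_too_small_errors(self, dr_scene):
        genome, pair, _ = dr_scene
        with pytest.raises(ValueError, match="exceeds"):
            build_junctions(genome, pair, genome.length)


class TestAligner:
    def test_verbatim_read_is_full_span_primary(self, dr_scene):
        genome, pair, _ = dr_scene
        jset = build_junctions(genome, pair, FLANK)
        read = jset.refs["ref_a"][50:-50]
        aln = KmerChainAligner(jset.refs).align("r", read)
        assert aln.reference == "ref_a"
        assert aln.strand == "+"
        assert (aln.ref_start, aln.ref_end) == (50, len(jset.refs["ref_a"]) - 50)
        assert (aln.query_start, aln.query_end) == (0, len(read))

    def test_revcomp_read_same_reference_minus_strand(self, dr_scene):
        genome, pair, _ = dr_scene
        jset = build_junctions(genome, pair, FLANK)
        read = reverse_complement(jset.refs["ref_a"][50:-50])
        aln = KmerChainAligner(jset.refs).align("r", read)
        assert aln.reference == "ref_a"
        assert aln.strand == "-"
        assert (aln.ref_start, aln.ref_end) == (50, len(jset.refs["ref_a"]) - 50)

    def test_unalignable_read_reported_unaligned(self, dr_scene):
        genome, pair, _ = dr_scene
        jset = build_junctions(genome, pair, FLANK)
        aln = KmerChainAligner(jset.refs).align("r", "ACGT" * 30)
        assert not aln.aligned

    def test_primary_agreement_with_truth_at_one_percent_error(self, dr_scene, rng):
        genome, pair, _ = dr_scene
        jset = build_junctions(genome, pair, FLANK)
        aligner = KmerChainAligner(jset.refs)
        labels = list(jset.refs)
        f, rep = jset.flank_len, jset.repeat_length
        n, correct = 1000, 0
        for i in range(n):
            label = labels[i % 4]
            ref = jset.refs[label]
            # reads covering the repeat plus >=50 bp of each flank are
            # unambiguous for their source reference
            start = int(rng.integers(f + rep + 50 - 400, f - 50 + 1))
            frag = list(ref[start : start + 400])
            for j in range(len(frag)):
                if rng.random() < 0.01:
                    frag[j] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(frag)
            aln = aligner.align(f"r{i}", read)
            if aln.reference == label:
                correct += 1
        assert correct / n >= 0.99

    def test_minimap2_adapter_agrees_with_internal_engine(self, dr_scene, rng):
        genome, pair, _ = dr_scene
        jset = build_junctions(genome, pair, FLANK)
        internal = KmerChainAligner(jset.refs)
        external = Minimap2Aligner(jset.refs, preset="map-hifi")
        reads = []
        for i in range(60):
            label = list(jset.refs)[i % 4]
            ref = jset.refs[label]
            # reads spanning the repeat with both flanks: unambiguous
            read = ref[60 : len(ref) - 60]
            frag = list(read)
            for j in range(len(frag)):
                if rng.random() < 0.005:
                    frag[j] = "ACGT"[int(rng.integers(0, 4))]
            reads.append((f"r{i}_{label}", "".join(frag)))
        got_int = [a.reference for a in internal.align_batch(reads)]
        got_ext = [a.reference for a in external.align_batch(reads)]
        agree = sum(a == b for a, b in zip(got_int, got_ext))
        assert agree >= 58  # near-total agreement between the two engines


class TestClassify:
    def _jset(self, dr_scene):
        genome, pair, _ = dr_scene
        return build_junctions(genome, pair, FLANK)

    def test_exact_boundary_is_assigned(self, dr_scene):
        jset = self._jset(dr_scene)
        f, rep = jset.flank_len, jset.repeat_length
        read = jset.refs["ref_a"][f - OVERLAP : f + rep + OVERLAP]
        aln = KmerChainAligner(jset.refs).align("r", read)
        assert classify_read(aln, jset, OVERLAP) == "ref_a"

    def test_one_base_short_is_unassigned(self, dr_scene):
        jset = self._jset(dr_scene)
        f, rep = jset.flank_len, jset.repeat_length
        read = jset.refs["ref_a"][f - (OVERLAP - 1) : f + rep + OVERLAP]
        aln = KmerChainAligner(jset.refs).align("r", read)
        assert classify_read(aln, jset, OVERLAP) == "unassigned"

    def test_repeat_only_read_never_assigned(self, dr_scene):
        jset = self._jset(dr_scene)
        f, rep = jset.flank_len, jset.repeat_length
        read = jset.refs["ref_a"][f : f + rep]  # pure repeat sequence
        aln = KmerChainAligner(jset.refs).align("r", read)
        assert classify_read(aln, jset, OVERLAP) == "unassigned"

    def test_overlap_larger_than_flank_errors(self, dr_scene):
        jset = self._jset(dr_scene)
        aln = KmerChainAligner(jset.refs).align("r", jset.refs["ref_a"])
        with pytest.raises(ValueError, match="exceeds flank_len"):
            classify_read(aln, jset, jset.flank_len + 1)

    def test_error_free_rule_satisfying_reads_classified_perfectly(self, dr_scene, rng):
        jset = self._jset(dr_scene)
        f, rep = jset.flank_len, jset.repeat_length
        aligner = KmerChainAligner(jset.refs)
        for label, ref in jset.refs.items():
            for _ in range(25):
                up = int(rng.integers(OVERLAP, f + 1))
                down = int(rng.integers(OVERLAP, f + 1))
                read = ref[f - up : f + rep + down]
                if rng.random() < 0.5:
                    read = reverse_complement(read)
                aln = aligner.align("r", read)
                assert classify_read(aln, jset, OVERLAP) == label


class TestSupportRates:
    @pytest.mark.parametrize(
        "n_ref,n_alt,pct_ref,pct_alt",
        [
            (104, 100, 50.98, 49.02),
            (174, 613, 22.11, 77.89),
            (822, 19, 97.74, 2.26),
            (1095, 16, 98.56, 1.44),
            (553, 8, 98.57, 1.43),
            (589, 5, 99.16, 0.84),
            (1055, 5, 99.53, 0.47),
            (0, 5, 0.00, 100.00),
        ],
    )
    def test_percentages_from_counts(self, n_ref, n_alt, pct_ref, pct_alt):
        table = support_rates([PairCounts("p", "IR", 100, n_ref, n_alt)])
        assert table.loc[0, "pct_reference"] == pct_ref
        assert table.loc[0, "pct_alternative"] == pct_alt

    def test_zero_assigned_reads_blank_rates(self):
        table = support_rates([PairCounts("p", "DR", 100, 0, 0)])
        assert table.loc[0, "n_reference"] == 0
        assert math.isnan(table.loc[0, "pct_reference"])

    def test_percentages_sum_to_100(self, rng):
        for _ in range(50):
            a, b = int(rng.integers(0, 2000)), int(rng.integers(1, 2000))
            table = support_rates([PairCounts("p", "DR", 10, a, b)])
            total = table.loc[0, "pct_reference"] + table.loc[0, "pct_alternative"]
            assert abs(total - 100.0) < 0.011  # equal up to rounding

    def test_swapping_reference_swaps_columns(self):
        t1 = support_rates([PairCounts("p", "IR", 10, 174, 613)])
        t2 = support_rates([PairCounts("p", "IR", 10, 613, 174)])
        assert t1.loc[0, "pct_reference"] == t2.loc[0, "pct_alternative"]
        assert t1.loc[0, "pct_alternative"] == t2.loc[0, "pct_reference"]


class TestCountSupport:
    def test_counts_junction_spanning_reads_only(self, dr_scene, rng):
        genome, pair, _ = dr_scene
        jset = build_junctions(genome, pair, FLANK)
        f, rep = jset.flank_len, jset.repeat_length
        reads = [
            ("spanning", jset.refs["alt_ab"][f - OVERLAP : f + rep + OVERLAP]),
            ("flank_only", jset.refs["ref_a"][:OVERLAP]),
            ("garbage", "ACGT" * 100),
        ]
        labels = count_support(reads, jset, OVERLAP)
        assert labels["alt_ab"] == 1
        assert labels["unassigned"] == 2
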