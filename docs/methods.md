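# Methods

## Scope and model

`mitorecomb` analyses the structural heterogeneity of circular organelle
genomes that arises from homologous recombination between dispersed repeat
pairs.  The model is deliberately minimal:

* A genome is one circular DNA molecule (or, after fission events, a small
  set of circles).  Two linear strings denote the same molecule iff one is
  a rotation of the other or of its reverse complement; molecule identity
  is decided by a canonical form (the lexicographically minimal such
  string, computed with Booth's least-rotation algorithm on the sequence
  and its reverse complement).
* Recombination acts at *repeat-copy granularity*.  Because the default
  repeat model is exact (identical copies), every crossover position inside
  a repeat yields the same product, so products are fully determined by the
  pair and the event kind: IR pair on one circle → inversion of the
  intervening arc (flip-flop); DR pair on one circle → fission into two
  subcircles each carrying one copy; one copy on each of two circles →
  fusion (the inverse of fission).  Each event conserves total length and
  base composition (up to complementation), and never destroys repeat
  content — properties asserted in the test suite.
* Read support for a configuration is junction evidence: a long read backs
  the configuration whose flank–repeat–flank reference it aligns to with
  sufficient unique flank on both sides.

## Repeat discovery

Maximal repeated segment pairs are found by seed-and-extend: 25-mer seeds
(or `min_len`-mers when smaller) are integer-encoded two bits per base;
forward and reverse-complement codes are reduced to a canonical code so a
single sort finds both DR and IR seed matches; seed matches are collapsed
per diagonal (anti-diagonal for IR) and extended maximally on the tripled
sequence.  The search runs on the doubled sequence so copies wrapping the
origin are found, and hits are de-duplicated modulo genome length.  A hit
is reported only if it cannot be extended on either side.  Copies are
merged into families by connected components (union–find over copy
intervals, merging intervals with ≥ 90% reciprocal overlap), strands
propagated through the pair graph (DR edges preserve strand, IR edges flip
it), families numbered 1…n by descending length (ties by first copy
position) and copies lettered a, b, c… by genome position with copy *a*
normalized to the '+' strand.

`min_identity` defaults to 1.0: exact copies are the clean substrate for
homologous recombination, and the exact setting makes discovery,
recombination products and junction references mutually consistent.  An
optional relaxation (e.g. 0.99) extends seeds through isolated mismatches
(no indels) while the running identity stays at or above the threshold;
it is a convenience for slightly diverged copies, with the caveat that a
mismatch every < 2·seed-length bases can defeat seeding.  `min_len` below
20 bp is refused because 100-kb genomes contain chance 15–18-mer
duplicates.

Nesting (a shorter family's copy wholly inside a longer family's copy,
modular containment) is reported with the inner copy's 1-based span within
the outer copy.  A copy pair is *shadowed* when both copies are nested
inside copies of one larger family: every read spanning such a junction
also spans the outer family's junction, so the pair has no junction
evidence of its own and is skipped (with a logged notice) in support
reporting.

The finder is validated against an independent oracle — an exhaustive
per-diagonal run-length scan of the doubled sequence against itself and
its reverse complement, with definitional while-loop re-extension — on
random planted instances up to 5 kb, and against the generator's planted
truth catalog on the 100-kb preset.

## Isomer enumeration and naming

`enumerate_forms` closes the master circle under a set of active pairs by
breadth-first search up to `max_events` (default 2, which covers the four
major forms generated by one IR and one DR pair).  In every product, repeat
copies are re-located by exact motif search on the doubled circle(s), so no
coordinate bookkeeping survives an event; copies are re-lettered by
position and only letter-pairs named in the active set may recombine.
Forms are de-duplicated by the multiset of canonical forms of their
circles, which collapses commuting event orders (inversion-then-fission and
fission-then-inversion yield one form).  Names follow the field's
convention: the founding form is MC1; an inversion at family 1 toggles
MC1 ⇌ MC2; any other event appends a superscript with the family number,
plus copy letters for families with more than two copies (MC1^2, MC2^2,
MC2^5ac).  The first-discovered name is kept for a de-duplicated form; in
the rare case two distinct forms derive the same name along different
paths, a `#k` disambiguator is appended.

Arc conventions: inversion reverse-complements the arc between the copies
that does not contain the origin; the test suite verifies the complementary
choice gives the same molecule by canonical equivalence.  Whether the
doubly rearranged forms are conceived as two-circle multipartite states or
re-fused master circles is left open by the underlying biology; here
fission products stay as two circles (the two-circle model), and fusion
events can re-join them during enumeration, with canonical de-duplication
absorbing the difference.

## Junction references and read classification

For each unshadowed pair, 3,000-bp flanks upstream and downstream of each
copy are extracted (wrapping across the origin as needed); the context of a
'-' copy is reverse-complemented so both copies present the repeat in '+'
orientation.  The four references are `ref_a = Ua+R+Da`, `ref_b = Ub+R+Db`,
`alt_ab = Ua+R+Db`, `alt_ba = Ub+R+Da`.  A flank that overlaps the partner
copy of the same pair triggers a warning (junction ambiguity); a flank that
fully contains the partner is an error.

A read's *primary alignment* is its best-scoring single collinear local
alignment over all references and strands.  The default engine indexes all
reference 15-mers, looks up strided read 15-mers (stride 5, the terminal
k-mer always included so error-free spans are exact), clusters anchors by
diagonal within a 300-bp band, enforces monotone reference order with a
greedy running-max filter, and scores chains by anchored query bases.  Ties
break deterministically: more anchored bases, then reference label in the
fixed order ref_a < ref_b < alt_ab < alt_ba, then '+' strand.  The engine
is reliable for reads within ~5% divergence; any object with the same
`align_batch` contract can substitute, and an adapter around the `minimap2`
executable is included and used as an independent cross-check in tests.

A read is assigned to its primary reference only if the alignment's
reference span covers at least `min_flank_overlap` (default 1,800 bp,
boundary inclusive) of the upstream flank *and* of the downstream flank;
otherwise it is unassigned.  With the largest nested covering repeat at
1,467 bp, 1,800 bp guarantees the read anchors in junction-unique sequence.
Reads assignable to junctions of several pairs count independently per
pair.  Support tables report pooled reference (ref_a+ref_b) and alternative
(alt_ab+alt_ba) counts and percentages rounded half-away-from-zero to two
decimals; per-label counts are kept internally and pooled only for the
printed columns.

## Read curation

* **Compartment extraction**: a read is assigned to the compartment (mito /
  nuclear / plastid / …) of its best primary alignment, and retained as
  mitochondrial only if its total query coverage on the mitogenome
  reference is ≥ 70%.  Coverage sums anchored query bases over all
  alignments to the compartment (both strands), so split alignments
  accumulate — a 50/50 chimera fails the threshold.
* **Duplex-like removal**: reads whose two halves align to the same
  reference region on opposite strands (reciprocal span overlap ≥ 80%, a
  package choice exposed as a flag) are removed as artifacts that cannot
  map linearly.  Because a half lying inside an inverted-repeat copy
  multi-maps to both copies, the duplex hypothesis is additionally tested
  by pinning each half to the strand opposite its partner's primary and
  re-asking for span agreement; reads genuinely crossing recombinant
  junctions are not flagged (tested).
* **Full-length accounting**: a read is "fully and linearly" explained by a
  form if one collinear chain (no strand switch, monotone coordinates, one
  diagonal band) aligns ≥ 95% of its bases to one of the form's circles;
  references are doubled internally so origin-crossing reads align
  linearly, and each read is counted once.  Short inter-anchor gaps
  (≤ 200 bp, sequencing-error seed losses) count as aligned; long gaps do
  not, so a chain that merely brackets a large unaligned stretch cannot
  pass.  The reference form is tested before the alternative, making the
  counts an ordered partition.  For the four major forms, the pair
  {MC1, MC2^2} jointly explains every junction: MC2-only junctions appear
  on MC2^2's large subcircle and MC1^2-only junctions on its fission
  circles, which is why that pair of references suffices.

## Synthetic data

`make_genome` plants an explicit repeat geometry on an i.i.d. uniform
background (a GC-content knob exists; the default is 25% each, since
composition only affects seed-collision rates).  The default preset is a
100,000-bp circle with a 9,000-bp IR pair, a 1,467-bp DR pair carrying a
188-bp repeat at motif positions 1,173–1,360 plus a free third copy in
inverted orientation, and three smaller pairs (564 bp IR, 317 bp IR,
161 bp DR) — the geometry the analysis is designed around, scaled to a
quarter-length genome so the full pipeline runs in seconds.  Boundary bases
flanking each planted copy are adjusted so no pair extends by chance:
the motif-oriented flanking base is made distinct across copies, mutating
only background positions (flanks inside another planted copy — the nested
case — are left alone, which is exactly the intended shadowing).  The
generator returns the ground-truth catalog, and the suite asserts the
finder reproduces it copy-for-copy.

`simulate_reads` draws, per read: a form by mixture proportion, a circle
within the form proportional to length, a uniform start, a lognormal length
(default mean 15 kb, σ = 0.25, truncated to [1 kb, 50 kb] — HiFi-like; an
ONT-like preset uses mean 25 kb with higher error), a uniform strand, and
i.i.d. substitution/insertion/deletion errors (each rate capped at 0.1).
Error modelling is intentionally simple: no homopolymer bias, no chimeras
beyond explicit duplex artifacts, no quality-value structure.  Passing
tests on this generator therefore demonstrates the *logic* of the pipeline
— junction bookkeeping, rate arithmetic, filter semantics — not robustness
to every real-platform artifact.  All generators are deterministic given
their seed, to the byte (fixed gzip headers).

## Numerical and procedural choices

* Coordinates are 0-based half-open internally; all report output is
  1-based inclusive.
* Percentage rounding is half-away-from-zero at two decimals, which
  reproduces published support tables from their integer counts.
* Binomial consistency is the closed-loop acceptance yardstick: a planted
  mixture proportion p must be recovered within 3·√(p(1−p)/n) for the n
  junction-assigned reads.  At the default depth (2,000 reads) a 9-kb
  repeat yields n of order 10², so the band is a few percentage points
  wide; that is the honest resolution of junction evidence at such depths.
* Problem sizes in the suite (100-kb preset genome, ≤ 5-kb oracle
  instances, 2,000-read mixtures) were chosen as the smallest scales at
  which every behaviour of interest — nesting, shadowing, wrap-around,
  mixture recovery — is exercised.

## Known limitations

* Exact-repeat default: diverged repeat pairs (< 99% identity) need the
  relaxed mode, whose seeding degrades with mismatch density; indel-bearing
  copies are out of scope.
* Tandem repeats are not modelled; overlapping copies are reported but
  recombination between them is refused.
* The enumeration names forms relative to the founding circle; after
  multiple events on families with ≥ 3 copies, copy letters refer to
  positions in the current form, not provenance on MC1.
* Stoichiometric dynamics (why the flip-flop sits near 50% while fission
  products dominate) are not modelled; mixtures are inputs, not outputs.
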