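"""Enumerate the isomeric genome forms generated by the long repeats.

Recombination between the two copies of an inverted repeat flips the
segment between them (flip-flop); recombination between direct-repeat
copies splits the circle into two subcircles.  Closing the master circle
under both long pairs yields the four major forms.
"""

import mitorecomb as mr
from mitorecomb.recombine import forms_manifest

genome, _ = mr.make_genome(mr.PAPER_LIKE_TOTAL_LEN, mr.paper_like_repeats(), seed=1)
catalog = mr.find_dispersed_repeats(genome)

# activate only the long (>1 kb) unshadowed pairs, the frequent recombiners
active = [p for p in catalog.all_pairs() if not p.shadowed and p.length >= 1000]
forms = mr.enumerate_forms(genome, catalog, active, max_events=2)

print(forms_manifest(forms).to_string(index=False))

# Expected: MC1 (the assembly), MC2 (flip-flop inversion at repeat-1), and
# the two-circle forms MC1^2 / MC2^2 (fission at repeat-2).  Total length is
# conserved in every form; MC2^2 reached via MC2-then-fission and via
# MC1^2-then-inversion is recognized as one form by canonical-form identity.
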