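"""Cross-species repeat arithmetic.

The largest inverted repeat of the *E. camaldulensis* mitogenome (repeat-1,
8,986 bp) aligns to four direct-repeat pairs in the published *E. grandis*
mitogenome.  Their combined length falling short of repeat-1 is consistent
with a split of an ancestral repeat; the published pair lengths are carried
here as reference constants for that bookkeeping.
"""

from __future__ import annotations

GRANDIS_REPEAT1_HOMOLOG_DR_BP = {
    "DR-1": 1148,
    "DR-2": 366,
    "DR-3": 4210,
    "DR-4": 206,
}

CAMALDULENSIS_REPEAT1_BP = 8986


def grandis_dr_total(lengths: dict[str, int] | None = None) -> int:
    """Combined length of the E. grandis DR pairs homologous to repeat-1."""
    lengths = GRANDIS_REPEAT1_HOMOLOG_DR_BP if lengths is None else lengths
    return sum(lengths.values())


def split_shortfall(lengths: dict[str, int] | None = None,
                    repeat1_bp: int = CAMALDULENSIS_REPEAT1_BP) -> dict[str, int]:
    """DR total vs the intact repeat-1 length, and the missing difference."""
    total = grandis_dr_total(lengths)
    return {
        "dr_total_bp": total,
        "repeat1_bp": repeat1_bp,
        "shortfall_bp": repeat1_bp - total,
    }
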