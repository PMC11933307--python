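"""Kozak-context extraction and tier classification.

The consensus used is RNN RNN AUG G: a purine at -3 and a G at +4 are
the dominant determinants.  Tiers:

* ``optimal``   — GCCACC at -6..-1 and G at +4 (the perfect context)
* ``strong``    — purine at -3 and G at +4 (but not optimal)
* ``adequate``  — exactly one of {purine at -3, G at +4}
* ``weak``      — neither
* ``indeterminate`` — -3 or +4 is missing (transcript edge) or N
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import SequenceRecord

OPTIMAL_WINDOW = "GCCACCAUGG"
PURINES = frozenset("AG")

TIERS = ("optimal", "strong", "adequate", "weak", "indeterminate")


@dataclass(frozen=True)
class KozakContext:
    """Sequence context of a start codon: positions -6..-1, codon, +4."""

    window: str
    minus3: str | None
    plus4: str | None
    tier: str


def _tier_from_parts(window: str, minus3: str | None, plus4: str | None) -> str:
    if minus3 is None or plus4 is None or minus3 == "N" or plus4 == "N":
        return "indeterminate"
    # optimal is judged on the flanks so near-cognate codons (e.g. a CUG
    # start) in a perfect GCCACC...G context classify as optimal too
    if len(window) == 10 and window[:6] == OPTIMAL_WINDOW[:6] and plus4 == "G":
        return "optimal"
    purine = minus3 in PURINES
    plus4_g = plus4 == "G"
    if purine and plus4_g:
        return "strong"
    if purine or plus4_g:
        return "adequate"
    return "weak"


def extract_context(transcript: SequenceRecord, tis_pos: int) -> KozakContext:
    """Extract the -6..+4 window around the start codon at ``tis_pos``.

    If the window runs off the 5' end the context is built from the
    available residues; the tier is computed only when both -3 and +4
    exist, otherwise it is ``indeterminate``.
    """
    n = len(transcript.seq)
    if not 1 <= tis_pos <= n - 2:
        raise IndexError(f"TIS position {tis_pos} out of bounds (length {n})")
    lo = max(1, tis_pos - 6)
    hi = min(n, tis_pos + 3)
    window = transcript.seq[lo - 1 : hi]
    minus3 = transcript.seq[tis_pos - 4] if tis_pos - 3 >= 1 else None
    plus4 = transcript.seq[tis_pos + 2] if tis_pos + 3 <= n else None
    return KozakContext(
        window=window,
        minus3=minus3,
        plus4=plus4,
        tier=_tier_from_parts(window, minus3, plus4),
    )


def classify_context(ctx: KozakContext) -> str:
    """Tier of an extracted context (pure function of the window)."""
    return _tier_from_parts(ctx.window, ctx.minus3, ctx.plus4)
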