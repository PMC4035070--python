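"""Anchored oligo-dT primer combinatorics.

Reverse transcription is primed with an oligo-dT primer terminated by a
degenerate dinucleotide so that synthesis starts exactly at the poly(A)
junction: a V base (A/C/G — not T) followed by N anchors the primer at the
junction, giving 12 primer species.  The redesign that suppresses oligo-dT
ligation artifacts splits this pool into 9 phosphorothioate-protected V*B
primers (B = C/G/T) plus 3 VA primers, whose second-strand products are
removed enzymatically.
"""

from __future__ import annotations

from itertools import product

from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = ["expand_degenerate", "oligo_dt_tail_variants", "anchored_tail_census"]


def expand_degenerate(code: str) -> list[str]:
    """All concrete DNA sequences matching an IUPAC degenerate code."""
    pools = []
    for ch in code.upper():
        if ch == "*":  # phosphorothioate linkage marker, no sequence content
            continue
        if ch not in ambiguous_dna_values:
            raise ValueError(f"unknown IUPAC code {ch!r}")
        pools.append(sorted(ambiguous_dna_values[ch]))
    return ["".join(p) for p in product(*pools)]


def oligo_dt_tail_variants(code: str = "VN") -> list[str]:
    """Concrete terminal dinucleotides of an anchored oligo-dT primer pool."""
    variants = expand_degenerate(code)
    if any(len(v) != 2 for v in variants):
        raise ValueError("anchored oligo-dT tails are dinucleotides")
    return variants


def anchored_tail_census() -> dict[str, int]:
    """Primer-pool sizes for the original (VN) and redesigned (V*B + VA) tails."""
    return {
        code: len(oligo_dt_tail_variants(code)) for code in ("VN", "V*B", "VA")
    }
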