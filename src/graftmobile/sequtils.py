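"""Small sequence helpers shared across the pipeline."""

from __future__ import annotations

import math
from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def shannon_entropy(seq: str) -> float:
    """Mononucleotide Shannon entropy of a sequence, in bits (0 for
    homopolymers, 2 for a perfectly balanced base composition)."""
    if not seq:
        return 0.0
    n = len(seq)
    h = 0.0
    for base in set(seq):
        p = seq.count(base) / n
        h -= p * math.log2(p)
    return h


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, matching how percentages are printed in
    report tables (e.g. 56.25 -> 56.3); Python's built-in round is
    banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
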