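"""Small shared helpers: printed-precision truncation, masking, complementation."""

from __future__ import annotations

import math

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def truncate(x: float, ndigits: int = 2) -> float:
    """Truncate toward zero at ``ndigits`` decimals (printed-report convention).

    Published per-kilobase frequencies and R/S ratios are printed truncated,
    not rounded (e.g. 10 events over 5,690 bp = 1.7575/kb prints as 1.75).
    A small epsilon guards against binary float droop (2.5 stored as
    2.4999...96 must still print 2.5).
    """
    if x != x or math.isinf(x):  # NaN / inf pass through
        return x
    scale = 10 ** ndigits
    eps = 1e-9 if x >= 0 else -1e-9
    return math.trunc(x * scale + eps) / scale


def is_transition(a: str, b: str) -> bool:
    return TRANSITION_PARTNER.get(a) == b


def masked_positions(length: int, masked_spans=()) -> set:
    """Expand 0-based half-open spans into a set of masked positions."""
    out: set = set()
    for start, end in masked_spans:
        if start < 0 or end > length or end < start:
            raise ValueError(f"masked span ({start},{end}) outside [0,{length})")
        out.update(range(start, end))
    return out


def check_alphabet(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise ValueError(f"{what} contains invalid characters: {sorted(bad)}")
    if not seq:
        raise ValueError(f"{what} is empty")
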