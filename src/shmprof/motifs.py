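"""AID hotspot (RGYW/WRCY) and polymerase-eta (WA/TW) motif analysis.

RGYW and WRCY (R = A/G, Y = C/T, W = A/T) are the classic AID deamination
hotspots; the mutable position is the G of RGYW and the C of WRCY, and the
two patterns are reverse complements of each other.  WA and TW mark A/T-
focused mutagenesis attributed to error-prone polymerase eta, with the A of
WA and the T of TW taken as the mutable position.  Scanning is on the given
(sense) strand; all overlapping hits are reported and one position may carry
several classes.  A mutation is "linked" to a class only when it sits exactly
on a hit's mutable position — a mutation elsewhere inside the window counts
separately as in-window, non-mutable.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from shmprof._util import revcomp

# class -> (regex, mutable offset within window, germline base at that offset)
MOTIF_PATTERNS = {
    "AID_RGYW": ("[AG]G[CT][AT]", 1, "G"),
    "AID_WRCY": ("[AT][AG]C[CT]", 2, "C"),
    "WA": ("[AT]A", 1, "A"),
    "TW": ("T[AT]", 0, "T"),
}

AID_CLASSES = ("AID_RGYW", "AID_WRCY")

# MutationRecord.motif_flags vocabulary
FLAG_FOR_CLASS = {"AID_RGYW": "AID", "AID_WRCY": "AID", "WA": "WA", "TW": "TW"}


@dataclass(frozen=True)
class MotifHit:
    motif_class: str
    window_start: int  # 0-based half-open window on the reference
    window_end: int
    mutable_position: int


def scan_motifs(reference: str, classes: Iterable = None) -> list:
    """All (overlapping) motif hits of the requested classes on the sense
    strand.  Windows containing N are skipped."""
    if classes is None:
        classes = MOTIF_PATTERNS.keys()
    classes = list(classes)
    for cls in classes:
        if cls not in MOTIF_PATTERNS:
            raise ValueError(f"unknown motif class {cls!r}")
    hits = []
    for cls in classes:
        pattern, offset, _base = MOTIF_PATTERNS[cls]
        width = len(pattern.replace("[AG]", ".").replace("[CT]", ".").replace("[AT]", "."))
        # lookahead regex so overlapping windows are all found
        for m in re.finditer(f"(?=({pattern}))", reference):
            start = m.start()
            hits.append(MotifHit(
                motif_class=cls, window_start=start, window_end=start + width,
                mutable_position=start + offset))
    hits.sort(key=lambda h: (h.window_start, h.motif_class))
    return hits


def scan_motifs_both_strands(reference: str, classes: Iterable = None) -> list:
    """Sense-strand hits plus reverse-strand hits mapped back to sense
    coordinates (class labels reflect the scanned strand's pattern)."""
    sense = scan_motifs(reference, classes)
    anti = []
    L = len(reference)
    for h in scan_motifs(revcomp(reference), classes):
        anti.append(MotifHit(
            motif_class=h.motif_class,
            window_start=L - h.window_end,
            window_end=L - h.window_start,
            mutable_position=L - 1 - h.mutable_position))
    return sorted(sense + anti, key=lambda h: (h.window_start, h.motif_class))


def motif_density(reference: str, motif_class: str, masked_spans=()) -> float:
    """Hits of one class (or 'AID' = RGYW+WRCY pooled) per 100 bp of unmasked
    sequence."""
    from shmprof._util import masked_positions

    masked = masked_positions(len(reference), masked_spans)
    unmasked_length = sum(1 for i in range(len(reference))
                          if i not in masked and reference[i] != "N")
    if unmasked_length == 0:
        raise ValueError("no unmasked sequence")
    classes = AID_CLASSES if motif_class == "AID" else (motif_class,)
    hits = [h for h in scan_motifs(reference, classes)
            if h.mutable_position not in masked]
    return 100.0 * len(hits) / unmasked_length


def motif_overlap(records: Sequence, hits: Sequence) -> dict:
    """Fraction of substitution mutations sitting on motif-mutable positions.

    For each class: a mutation counts iff its reference position equals some
    hit's mutable position of that class *and* its germline base is the
    class's mutable base (the G of RGYW, the C of WRCY, the A of WA, the T of
    TW).  Mutations inside a window but off the mutable position are tallied
    as in-window, non-mutable.  Pooled 'AID' and 'WA_TW' fractions are also
    reported.  Fractions are over substitution records only.
    """
    subs = [r for r in records if r.event_class == "substitution"]
    n = len(subs)
    mutable = {cls: set() for cls in MOTIF_PATTERNS}
    windows = {cls: [] for cls in MOTIF_PATTERNS}
    for h in hits:
        mutable[h.motif_class].add(h.mutable_position)
        windows[h.motif_class].append((h.window_start, h.window_end, h.mutable_position))

    linked = Counter()
    in_window_non_mutable = Counter()
    aid_positions = mutable["AID_RGYW"] | mutable["AID_WRCY"]
    wa_tw_positions = mutable["WA"] | mutable["TW"]
    for r in subs:
        for cls in MOTIF_PATTERNS:
            base = MOTIF_PATTERNS[cls][2]
            if r.position in mutable[cls] and r.from_base == base:
                linked[cls] += 1
            elif any(ws <= r.position < we and r.position != mp
                     for ws, we, mp in windows[cls]):
                in_window_non_mutable[cls] += 1
        if r.position in aid_positions and r.from_base in "GC":
            linked["AID"] += 1
        if r.position in wa_tw_positions and r.from_base in "AT":
            linked["WA_TW"] += 1

    out = {}
    for key in list(MOTIF_PATTERNS) + ["AID", "WA_TW"]:
        out[key] = {
            "linked": linked[key],
            "fraction": linked[key] / n if n else 0.0,
        }
        if key in MOTIF_PATTERNS:
            out[key]["in_window_non_mutable"] = in_window_non_mutable[key]
    out["n_substitutions"] = n
    return out


def annotate_motif_flags(records: Sequence, hits: Sequence) -> None:
    """Fill MutationRecord.motif_flags ({AID, WA, TW}) in place from hits."""
    by_class: dict = {}
    for h in hits:
        by_class.setdefault(h.motif_class, set()).add(h.mutable_position)
    for r in records:
        if r.event_class != "substitution":
            continue
        for cls, positions in by_class.items():
            base = MOTIF_PATTERNS[cls][2]
            if r.position in positions and r.from_base == base:
                r.motif_flags.add(FLAG_FOR_CLASS[cls])
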