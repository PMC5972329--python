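"""Candidate J gene-segment discovery in genomic scaffolds.

A J exon candidate must (i) translate, in some frame, through the conserved
core motif FGXG (default relaxed to [FW]G.G to admit slightly modified
cores), (ii) carry an upstream 12-type recombination signal sequence —
nonamer, ~12 nt spacer, heptamer ending immediately 5' of the exon, with the
invariant heptamer prefix CAC — and (iii) end at a GT splice donor.  Both
strands are scanned; overlapping candidates are deduplicated by score, then
leftmost start.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from shmprof._util import revcomp

HEPTAMER_CONSENSUS = "CACAGTG"
NONAMER_CONSENSUS = "ACAAAAACC"


@dataclass
class JScanConfig:
    core_pattern: str = "[FW]G.G"   # peptide regex for the J core motif
    exon_min: int = 36              # nt
    exon_max: int = 75
    heptamer_max_mismatch: int = 1  # outside the invariant CAC prefix
    nonamer_max_mismatch: int = 2
    spacer_center: int = 12         # 12-RSS with ±tolerance
    spacer_tolerance: int = 1
    both_strands: bool = True

    def __post_init__(self) -> None:
        lo = self.spacer_center - self.spacer_tolerance
        hi = self.spacer_center + self.spacer_tolerance
        if lo < 10 or hi > 25:
            raise ValueError(f"spacer band [{lo},{hi}] outside the allowed [10,25]")
        if self.exon_min < 12 or self.exon_max < self.exon_min:
            raise ValueError("invalid exon length band")

    @property
    def spacer_range(self):
        return range(self.spacer_center - self.spacer_tolerance,
                     self.spacer_center + self.spacer_tolerance + 1)


@dataclass
class JSegmentCandidate:
    scaffold_id: str
    exon_start: int  # scaffold coordinates, 0-based half-open, plus strand
    exon_end: int
    strand: str
    frame: int
    core_motif: str
    exon_sequence: str
    heptamer_start: int  # strand-local coordinate of the RSS heptamer
    heptamer_seq: str
    heptamer_mismatches: int
    spacer_length: int
    nonamer_seq: str
    nonamer_mismatches: int
    splice_donor_pos: int
    score: int


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _translate(seq: str) -> str:
    from shmprof.mutations import CODON_TO_AA

    return "".join(CODON_TO_AA.get(seq[i:i + 3], "X")
                   for i in range(0, len(seq) - 2, 3))


def _scan_strand(seq: str, scaffold_id: str, strand: str, total_len: int,
                 config: JScanConfig) -> list:
    core_re = re.compile(config.core_pattern)
    strict_re = re.compile("FG.G")
    out = []
    for h in range(9 + min(config.spacer_range), len(seq) - 7 - config.exon_min - 2):
        hept = seq[h:h + 7]
        if not hept.startswith("CAC"):
            continue
        hept_mm = _mismatches(hept[3:], HEPTAMER_CONSENSUS[3:])
        if hept_mm > config.heptamer_max_mismatch:
            continue
        # best upstream nonamer over the spacer band
        best_nona = None
        for spacer in config.spacer_range:
            ns = h - spacer - 9
            if ns < 0:
                continue
            nona = seq[ns:ns + 9]
            mm = _mismatches(nona, NONAMER_CONSENSUS)
            if mm <= config.nonamer_max_mismatch:
                key = (mm, abs(spacer - config.spacer_center))
                if best_nona is None or key < best_nona[0]:
                    best_nona = (key, spacer, nona, mm)
        if best_nona is None:
            continue
        _, spacer, nona_seq, nona_mm = best_nona

        exon_start = h + 7
        found = None
        for L in range(config.exon_max, config.exon_min - 1, -1):  # maximal window
            exon_end = exon_start + L
            if exon_end + 2 > len(seq):
                continue
            if seq[exon_end:exon_end + 2] != "GT":
                continue
            exon = seq[exon_start:exon_end]
            if "N" in exon:
                continue
            for frame in range(3):
                peptide = _translate(exon[frame:])
                m = core_re.search(peptide)
                if m:
                    found = (L, frame, m.group(0), exon)
                    break
            if found:
                break
        if not found:
            continue
        L, frame, core, exon = found
        score = (2 - hept_mm) + (2 - nona_mm) + (1 if strict_re.fullmatch(core) else 0)
        if strand == "+":
            plus_start, plus_end = exon_start, exon_start + L
        else:
            plus_start, plus_end = total_len - (exon_start + L), total_len - exon_start
        out.append(JSegmentCandidate(
            scaffold_id=scaffold_id, exon_start=plus_start, exon_end=plus_end,
            strand=strand, frame=frame, core_motif=core, exon_sequence=exon,
            heptamer_start=h, heptamer_seq=hept, heptamer_mismatches=hept_mm,
            spacer_length=spacer, nonamer_seq=nona_seq, nonamer_mismatches=nona_mm,
            splice_donor_pos=exon_start + L, score=score))
    return out


def scan_j_segments(scaffold: str, config: Optional[JScanConfig] = None,
                    scaffold_id: str = "scaffold") -> list:
    """Scan one scaffold (both strands by default) for J-segment candidates.

    Overlapping candidates are deduplicated keeping the highest score, ties
    broken by leftmost exon start then plus strand.
    """
    config = config or JScanConfig()
    if len(scaffold) < 200:
        raise ValueError("scaffold shorter than 200 nt")
    scaffold = scaffold.upper()
    candidates = _scan_strand(scaffold, scaffold_id, "+", len(scaffold), config)
    if config.both_strands:
        candidates += _scan_strand(revcomp(scaffold), scaffold_id, "-",
                                   len(scaffold), config)
    candidates.sort(key=lambda c: (-c.score, c.exon_start, c.strand))
    kept = []
    for cand in candidates:
        if any(cand.exon_start < k.exon_end and k.exon_start < cand.exon_end
               for k in kept):
            continue
        kept.append(cand)
    kept.sort(key=lambda c: c.exon_start)
    return kept


def build_j_library(candidates: Sequence, naming_prefix: str = "J") -> list:
    """Ordered (j_id, exon_sequence) library from deduplicated candidates.

    Ids are assigned 5'->3' on the plus strand; minus-strand candidates
    contribute their already strand-corrected exon sequence.  Duplicate
    coordinates collapse to a single entry.
    """
    seen = set()
    unique = []
    for cand in sorted(candidates, key=lambda c: (c.exon_start, c.exon_end)):
        key = (cand.exon_start, cand.exon_end)
        if key in seen:
            continue
        seen.add(key)
        unique.append(cand)
    width = max(2, len(str(len(unique))))
    return [(f"{naming_prefix}{i:0{width}d}", cand.exon_sequence)
            for i, cand in enumerate(unique, start=1)]


def candidates_frame(candidates: Sequence) -> pd.DataFrame:
    """GFF3-like TSV payload (1-based inclusive coordinates as is standard)."""
    rows = []
    for c in candidates:
        rows.append({
            "scaffold": c.scaffold_id,
            "start_1based": c.exon_start + 1,
            "end": c.exon_end,
            "strand": c.strand,
            "score": c.score,
            "attributes": (f"core={c.core_motif};frame={c.frame};"
                           f"hept_mm={c.heptamer_mismatches};"
                           f"nona_mm={c.nonamer_mismatches};"
                           f"spacer={c.spacer_length}"),
        })
    return pd.DataFrame(rows)
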