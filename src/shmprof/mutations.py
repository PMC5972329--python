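"""Mutation calling and classification against a (sub)group germline.

Each clone is compared to its germline baseline; every substitution column
and every contiguous gap run becomes one event.  Substitutions are classed as
transition/transversion and — by translating the germline codon with only
that substitution applied — as replacement, synonymous or nonsense.  Indels
whose length is not a multiple of three are frameshifts.  Allelic positions
and N columns never yield events.  Summaries reproduce the standard clone-set
accounting (events, events per 1,000 surveyed bp, R/S and Ti/Tv ratios, all
printed truncated to two decimals with full precision kept internally).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from shmprof._util import is_transition, masked_positions, truncate
from shmprof.germline import GermlineReference, align_clone
from shmprof.seqio import RegionMap

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_STANDARD.forward_table)
CODON_TO_AA.update({codon: "*" for codon in _STANDARD.stop_codons})


def translate(seq: str) -> str:
    """Translate with the standard code; codons containing N give 'X'."""
    return "".join(
        CODON_TO_AA.get(seq[i:i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


@dataclass
class MutationRecord:
    clone_id: str
    position: int  # reference coordinate (0-based)
    from_base: str  # "" for insertions
    to_base: str    # "" for deletions
    event_class: str  # substitution | insertion | deletion
    titv: str         # transition | transversion | n/a
    effect: str       # replacement | synonymous | nonsense | frameshift | noncoding
    region: str = ""
    motif_flags: set = field(default_factory=set)

    @property
    def indel_length(self) -> int:
        if self.event_class == "insertion":
            return len(self.to_base)
        if self.event_class == "deletion":
            return len(self.from_base)
        return 0


def _codon_effect(ref: str, pos: int, to_base: str, frame: int) -> str:
    """Effect of a single substitution, all other positions germline."""
    coding_start = frame
    coding_end = frame + 3 * ((len(ref) - frame) // 3)
    if pos < coding_start or pos >= coding_end:
        return "noncoding"
    codon_index = (pos - coding_start) // 3
    cstart = coding_start + 3 * codon_index
    codon = ref[cstart:cstart + 3]
    if "N" in codon:
        return "noncoding"
    offset = pos - cstart
    mutant = codon[:offset] + to_base + codon[offset + 1:]
    aa_ref = CODON_TO_AA.get(codon, "X")
    aa_mut = CODON_TO_AA.get(mutant, "X")
    if aa_mut == aa_ref:
        return "synonymous"
    if aa_mut == "*":
        return "nonsense"
    return "replacement"


def _fast_substitutions(clone_seq: str, ref_seq: str):
    """Equal-length column compare without alignment (no indels possible)."""
    a = np.frombuffer(clone_seq.encode(), dtype=np.uint8)
    b = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
    diff = np.nonzero(a != b)[0]
    return [(int(i), ref_seq[i], clone_seq[i]) for i in diff]


def call_mutations(clone, germline: GermlineReference,
                   region_map: Optional[RegionMap] = None,
                   masked_spans=()) -> list:
    """Call all substitution and indel events of one clone.

    Allelic positions of the germline are skipped (they are allelic, not
    somatic), as are columns where either sequence has N and any masked
    (e.g. primer-covered) span.  Substitutions downstream of a frameshift are
    still called at the nucleotide level but get effect ``noncoding``.
    """
    ref = germline.sequence
    seq = clone.sequence if hasattr(clone, "sequence") else str(clone)
    clone_id = getattr(clone, "clone_id", "")
    if len(seq) < len(ref) / 2:
        warnings.warn(f"clone {clone_id!r} covers less than half the reference; "
                      "processed over the aligned span only")

    if len(seq) == len(ref):
        subs = _fast_substitutions(seq, ref)
        insertions, deletions = [], []
    else:
        aln = align_clone(seq, germline)
        subs, insertions, deletions = aln.substitutions, aln.insertions, aln.deletions

    masked = masked_positions(len(ref), masked_spans)
    skip = germline.allelic_position_set | masked
    frame = germline.frame_offset

    records = []
    fs_positions = []
    for pos, inserted in insertions:
        effect = "frameshift" if len(inserted) % 3 else "replacement"
        if effect == "frameshift":
            fs_positions.append(pos)
        records.append(MutationRecord(
            clone_id=clone_id, position=pos, from_base="", to_base=inserted,
            event_class="insertion", titv="n/a", effect=effect,
            region=region_map.region_at(pos) if region_map else ""))
    for start, end in deletions:
        effect = "frameshift" if (end - start) % 3 else "replacement"
        if effect == "frameshift":
            fs_positions.append(start)
        records.append(MutationRecord(
            clone_id=clone_id, position=start, from_base=ref[start:end], to_base="",
            event_class="deletion", titv="n/a", effect=effect,
            region=region_map.region_at(start) if region_map else ""))
    first_fs = min(fs_positions) if fs_positions else None

    for pos, from_base, to_base in subs:
        if pos in skip or from_base == "N" or to_base == "N":
            continue
        if first_fs is not None and pos > first_fs:
            effect = "noncoding"
        else:
            effect = _codon_effect(ref, pos, to_base, frame)
        records.append(MutationRecord(
            clone_id=clone_id, position=pos, from_base=from_base, to_base=to_base,
            event_class="substitution",
            titv="transition" if is_transition(from_base, to_base) else "transversion",
            effect=effect,
            region=region_map.region_at(pos) if region_map else ""))
    records.sort(key=lambda r: (r.position, r.event_class))
    return records


def surveyed_bases(clone, germline: GermlineReference, masked_spans=()) -> int:
    """Reference bases surveyed for this clone: aligned columns minus masked
    spans and minus columns where either sequence has N."""
    ref = germline.sequence
    seq = clone.sequence if hasattr(clone, "sequence") else str(clone)
    masked = masked_positions(len(ref), masked_spans)
    if len(seq) == len(ref):
        return sum(1 for i in range(len(ref))
                   if i not in masked and ref[i] != "N" and seq[i] != "N")
    aln = align_clone(seq, germline)
    n = 0
    deleted = set()
    for start, end in aln.deletions:
        deleted.update(range(start, end))
    for i in range(aln.ref_start, aln.ref_end):
        if i in masked or i in deleted or ref[i] == "N":
            continue
        n += 1
    # N columns on the clone side are rare; subtract them from the paired span
    n -= sum(1 for i, rb, cb in aln.substitutions
             if aln.ref_start <= i < aln.ref_end and (cb == "N" or rb == "N")
             and i not in masked)
    return n


@dataclass
class MutationSummary:
    """Clone-set level accounting of somatic mutation events."""

    n_clones: int
    n_bp: int
    n_events: int
    freq_per_kb: float
    replacement: int
    silent: int
    nonsense: int
    noncoding: int
    transitions: int
    transversions: int
    frameshifts: int
    inframe_indels: int
    rs_ratio: Optional[float]
    titv_ratio: Optional[float]
    per_region: dict

    def printed(self) -> dict:
        """Report-facing values truncated toward zero at two decimals."""
        return {
            "freq_per_kb": truncate(self.freq_per_kb, 2),
            "rs_ratio": None if self.rs_ratio is None else truncate(self.rs_ratio, 2),
            "titv_ratio": None if self.titv_ratio is None else truncate(self.titv_ratio, 2),
        }


def summarize(records: Sequence, n_clones: int, n_bp: int) -> MutationSummary:
    """Aggregate event records into the standard clone-set summary.

    ``n_bp`` is the total surveyed reference-aligned bases over all clones
    (primer spans and N columns excluded); frequencies are per 1,000 bp.
    Frameshifts count toward total events but never toward Ti/Tv or R/S.
    """
    if n_bp <= 0:
        raise ValueError("n_bp must be positive")
    subs = [r for r in records if r.event_class == "substitution"]
    indels = [r for r in records if r.event_class != "substitution"]
    replacement = sum(1 for r in subs if r.effect == "replacement")
    silent = sum(1 for r in subs if r.effect == "synonymous")
    nonsense = sum(1 for r in subs if r.effect == "nonsense")
    noncoding = sum(1 for r in subs if r.effect == "noncoding")
    transitions = sum(1 for r in subs if r.titv == "transition")
    transversions = sum(1 for r in subs if r.titv == "transversion")
    frameshifts = sum(1 for r in indels if r.effect == "frameshift")
    inframe = len(indels) - frameshifts
    n_events = len(records)

    per_region: dict = {}
    for r in records:
        slot = per_region.setdefault(r.region, Counter())
        slot["n_events"] += 1
        if r.event_class == "substitution" and r.effect in ("replacement", "synonymous"):
            slot[r.effect] += 1
    per_region = {k: dict(v) for k, v in per_region.items()}

    return MutationSummary(
        n_clones=n_clones, n_bp=n_bp, n_events=n_events,
        freq_per_kb=1000.0 * n_events / n_bp,
        replacement=replacement, silent=silent, nonsense=nonsense,
        noncoding=noncoding, transitions=transitions, transversions=transversions,
        frameshifts=frameshifts, inframe_indels=inframe,
        rs_ratio=(replacement / silent) if silent else None,
        titv_ratio=(transitions / transversions) if transversions else None,
        per_region=per_region,
    )


BASES = ("A", "C", "G", "T")


def substitution_spectrum(records: Sequence) -> pd.DataFrame:
    """4x4 from->to substitution count matrix (rows = germline base)."""
    matrix = pd.DataFrame(0, index=list(BASES), columns=list(BASES))
    for r in records:
        if r.event_class == "substitution" and r.from_base in BASES and r.to_base in BASES:
            matrix.loc[r.from_base, r.to_base] += 1
    return matrix


def window_profile(records: Sequence, n_clones: int, length: int,
                   window: int = 20, masked_spans=(), start: int = 0) -> pd.DataFrame:
    """Per-window, per-effect-class mutation frequency track.

    Non-overlapping windows of ``window`` bp from ``start``;
    frequency = events of the class in the window (over all clones) divided by
    (unmasked window positions x n_clones).  Events at masked (primer)
    positions are excluded everywhere.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    masked = masked_positions(length, masked_spans)
    classes = sorted({r.effect for r in records}) or ["replacement", "synonymous"]
    counts: dict = {}
    for r in records:
        if r.position in masked or not start <= r.position < length:
            continue
        widx = (r.position - start) // window
        counts[(widx, r.effect)] = counts.get((widx, r.effect), 0) + 1
    rows = []
    n_windows = max(1, -(-(length - start) // window))
    for widx in range(n_windows):
        wstart = start + widx * window
        wend = min(wstart + window, length)
        n_sites = sum(1 for p in range(wstart, wend) if p not in masked)
        for cls in classes:
            count = counts.get((widx, cls), 0)
            freq = count / (n_sites * n_clones) if n_sites and n_clones else 0.0
            rows.append({
                "window_start_1based": wstart + 1, "window_end": wend,
                "effect": cls, "count": count, "n_sites": n_sites,
                "frequency": freq,
            })
    return pd.DataFrame(rows)


def functional_status(clone, germline: GermlineReference,
                      region_map: Optional[RegionMap] = None) -> str:
    """Classify one clone as in_frame, stop_codon or frameshift.

    Frameshift: the running net indel length upstream of the constant region
    leaves the reading frame (not a multiple of 3) at any point.  Otherwise a
    premature stop anywhere before the final codon -> stop_codon; else
    in_frame.
    """
    ref = germline.sequence
    seq = clone.sequence if hasattr(clone, "sequence") else str(clone)
    frame = germline.frame_offset
    constant_start = len(ref)
    if region_map is not None:
        c_regions = [s for name, s, _ in region_map.regions if name.startswith("C-")]
        if c_regions:
            constant_start = min(c_regions)

    if len(seq) != len(ref):
        aln = align_clone(seq, germline)
        events = [(pos, len(inserted)) for pos, inserted in aln.insertions]
        events += [(s, -(e - s)) for s, e in aln.deletions]
        running = 0
        for pos, delta in sorted(events):
            if pos >= constant_start:
                break
            running += delta
            if running % 3 != 0:
                return "frameshift"
        clone_start = frame + max(0, -_leading_shift(aln, frame))
    else:
        clone_start = frame
    protein = translate(seq[clone_start:])
    # a stop at the final translated codon is a legitimate terminator
    if "*" in protein[:-1]:
        return "stop_codon"
    return "in_frame"


def _leading_shift(aln, frame: int) -> int:
    """Net indel bases 5' of the frame start (keeps translation in register)."""
    shift = 0
    for pos, inserted in aln.insertions:
        if pos <= frame:
            shift += len(inserted)
    for s, e in aln.deletions:
        if e <= frame:
            shift -= e - s
    return shift


def nonfunctional_fraction(statuses: Sequence) -> float:
    """Fraction of clones that are not in frame (stop codon or frameshift)."""
    statuses = list(statuses)
    if not statuses:
        raise ValueError("empty status list")
    return sum(1 for s in statuses if s != "in_frame") / len(statuses)


@dataclass
class RateComparison:
    ratio: Optional[float]
    p_value: Optional[float]
    flag: str = ""


def compare_rates(target: MutationSummary, control: MutationSummary) -> RateComparison:
    """Per-kilobase rate ratio with a conditional binomial two-sample test.

    Conditional on the total event count, events fall in the target with
    probability n_bp_target / (n_bp_target + n_bp_control) under equal rates;
    the two-sided exact binomial p-value tests that null.
    """
    if target.n_bp <= 0 or control.n_bp <= 0:
        raise ValueError("both summaries need n_bp > 0")
    total = target.n_events + control.n_events
    if total == 0:
        return RateComparison(ratio=None, p_value=None, flag="no_events")
    p0 = target.n_bp / (target.n_bp + control.n_bp)
    p_value = stats.binomtest(target.n_events, total, p0).pvalue
    if control.n_events == 0:
        return RateComparison(ratio=None, p_value=p_value, flag="control_rate_zero")
    return RateComparison(ratio=target.freq_per_kb / control.freq_per_kb,
                          p_value=p_value)
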