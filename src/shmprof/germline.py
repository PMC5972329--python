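"""Germline/allele inference and clone-pool structure.

A clone pool from one individual is reduced to a consensus baseline; columns
where the second-most-frequent base is common (default >= 30% of clones) are
treated as allelic rather than somatic — the two-subgroup, ~50/50 signature of
a heterozygous locus — and are excluded from downstream mutation counts.
This module also genotypes constant-region allotypes against diagnostic-
position profiles, flags PCR-jumping chimeras (single-crossover hybrids of two
alleles), clusters V sequences into families at a nucleotide-identity
threshold, and assigns J segments by ungapped scan.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align

from shmprof._util import check_alphabet
from shmprof.seqio import CloneRecord


class InsufficientDataError(ValueError):
    """Too few clones to infer a germline baseline."""


class AmbiguousConsensusError(ValueError):
    """Columns with three-way ties cannot be resolved into major/minor bases."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"three-way base ties at columns {self.columns}")


@dataclass
class GermlineReference:
    """Inferred or supplied baseline sequence with its allelic positions.

    ``allelic_positions`` holds (position, major_base, minor_base,
    minor_frequency) tuples; those positions are excluded from somatic-mutation
    calling downstream.
    """

    sequence: str
    allelic_positions: list = field(default_factory=list)
    frame_offset: int = 0
    source: str = "supplied"

    def __post_init__(self) -> None:
        check_alphabet(self.sequence, "germline reference")
        for pos, major, minor, freq in self.allelic_positions:
            if not 0 <= pos < len(self.sequence):
                raise ValueError(f"allelic position {pos} outside reference")
            if not 0 < freq <= 0.5:
                raise ValueError(f"minor frequency {freq} not in (0, 0.5]")

    @property
    def allelic_position_set(self) -> set:
        return {p for p, *_ in self.allelic_positions}


@dataclass
class AllotypeProfile:
    """A constant-region allotype defined by its diagnostic positions."""

    allotype_id: str
    diagnostic_positions: list  # of (position, base)

    def __post_init__(self) -> None:
        if not self.diagnostic_positions:
            raise ValueError(f"allotype {self.allotype_id}: no diagnostic positions")

    def mismatches(self, sequence: str) -> int:
        return sum(
            1 for pos, base in self.diagnostic_positions
            if pos >= len(sequence) or sequence[pos] != base
        )


@dataclass
class GenotypeCall:
    individual_id: str
    alleles: tuple  # unordered pair of allotype ids
    support: dict  # allotype_id -> clone count
    unassigned: int = 0
    novel_candidates: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


@dataclass
class AlignmentResult:
    """Column-mapped global alignment of a clone against a reference."""

    score: float
    ref_start: int  # aligned span on the reference (terminal gaps excluded)
    ref_end: int
    substitutions: list  # (ref_pos, ref_base, clone_base)
    insertions: list     # (ref_pos, inserted_sequence) — insertion 5' of ref_pos
    deletions: list      # (ref_start, ref_end) deleted from the clone
    n_matches: int
    n_columns: int       # paired + internal gap columns

    @property
    def identity(self) -> float:
        """Matches over aligned columns, terminal gaps excluded."""
        return self.n_matches / self.n_columns if self.n_columns else 0.0


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    # affine internal gaps: first gap base -4, each further base -1
    if hasattr(aligner, "open_internal_gap_score"):
        aligner.open_internal_gap_score = -4.0
        aligner.extend_internal_gap_score = -1.0
    else:  # older Biopython attribute names
        aligner.internal_open_gap_score = -4.0
        aligner.internal_extend_gap_score = -1.0
    # terminal gaps are linear at -1: for a fragment the total end-gap length
    # is fixed by the length difference, so this acts as a constant offset
    # while preventing degenerate overhang alignments on short sequences
    aligner.end_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def align_clone(clone, reference) -> AlignmentResult:
    """Globally align a clone to a reference and extract per-column events.

    Scoring: match +1, mismatch -1, internal gaps -4 for the first base and
    -1 per further base, terminal gaps -1 per base (linear).  Traceback is
    deterministic (first optimal alignment).  Columns are reported in
    reference coordinates; terminal overhangs are not events.
    """
    ref_seq = reference.sequence if hasattr(reference, "sequence") else str(reference)
    clone_seq = clone.sequence if hasattr(clone, "sequence") else str(clone)
    if not ref_seq or not clone_seq:
        raise ValueError("cannot align empty sequence")

    alignment = _ALIGNER.align(ref_seq, clone_seq)[0]
    t_blocks, q_blocks = alignment.aligned

    substitutions, insertions, deletions = [], [], []
    n_matches = 0
    n_columns = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for i in range(te - ts):
            rb, cb = ref_seq[ts + i], clone_seq[qs + i]
            n_columns += 1
            if rb == cb:
                n_matches += 1
            else:
                substitutions.append((ts + i, rb, cb))
    for k in range(len(t_blocks) - 1):
        t_gap_start, t_gap_end = t_blocks[k][1], t_blocks[k + 1][0]
        q_gap_start, q_gap_end = q_blocks[k][1], q_blocks[k + 1][0]
        if t_gap_end > t_gap_start:
            deletions.append((t_gap_start, t_gap_end))
            n_columns += t_gap_end - t_gap_start
        if q_gap_end > q_gap_start:
            insertions.append((t_gap_end, clone_seq[q_gap_start:q_gap_end]))
            n_columns += q_gap_end - q_gap_start

    ref_start = int(t_blocks[0][0]) if len(t_blocks) else 0
    ref_end = int(t_blocks[-1][1]) if len(t_blocks) else 0
    return AlignmentResult(
        score=float(alignment.score),
        ref_start=ref_start,
        ref_end=ref_end,
        substitutions=substitutions,
        insertions=insertions,
        deletions=deletions,
        n_matches=n_matches,
        n_columns=n_columns,
    )


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Nucleotide identity from a global alignment: matches over aligned
    columns, terminal gaps excluded."""
    return align_clone(seq_a, seq_b).identity


def _column_bases(clones: Sequence, scaffold: str) -> list:
    """Project each clone onto scaffold columns; returns per-column base lists
    (gaps and terminal overhangs contribute nothing)."""
    columns = [[] for _ in range(len(scaffold))]
    for clone in clones:
        seq = clone.sequence
        if seq == scaffold:
            for i, b in enumerate(seq):
                columns[i].append(b)
            continue
        aln = align_clone(clone, scaffold)
        # replay the paired blocks to place clone bases on scaffold columns
        alignment = _ALIGNER.align(scaffold, seq)[0]
        for (ts, te), (qs, qe) in zip(*alignment.aligned):
            for i in range(te - ts):
                columns[ts + i].append(seq[qs + i])
    return columns


def infer_germline(clones: Sequence, allele_threshold: float = 0.3,
                   frame_offset: int = 0) -> GermlineReference:
    """Column-consensus germline with allelic-position detection.

    The consensus base of each column is the most frequent base; a column
    whose second-most-frequent base reaches ``allele_threshold`` of the
    (non-N) clones is recorded as allelic — capturing the "two alternative
    nucleotides at roughly 50% each" signature of heterozygosity — and is
    excluded from somatic-mutation counts downstream.
    """
    clones = list(clones)
    if len(clones) < 4:
        raise InsufficientDataError(f"need >=4 clones to infer a germline, got {len(clones)}")
    if not 0 < allele_threshold <= 0.5:
        raise ValueError("allele_threshold must be in (0, 0.5]")

    lengths = Counter(len(c) for c in clones)
    if len(lengths) == 1:
        scaffold = clones[0].sequence
        columns = [[c.sequence[i] for c in clones] for i in range(len(scaffold))]
    else:
        # scaffold = first clone of the modal length: an indel-bearing outlier
        # must not impose its coordinates on the whole pool
        modal_length = lengths.most_common(1)[0][0]
        scaffold = next(c.sequence for c in clones if len(c) == modal_length)
        columns = _column_bases(clones, scaffold)

    consensus = []
    allelic = []
    ambiguous_columns = []
    for pos, bases in enumerate(columns):
        counts = Counter(b for b in bases if b in "ACGT")
        if not counts:
            consensus.append("N")
            continue
        ranked = counts.most_common()
        top_count = ranked[0][1]
        tied = sorted(b for b, n in ranked if n == top_count)
        if len(tied) >= 3:
            ambiguous_columns.append(pos)
            consensus.append(tied[0])
            continue
        major = tied[0]  # alphabetical tie-break for a 50/50 column
        consensus.append(major)
        total = sum(counts.values())
        rest = [(b, n) for b, n in ranked if b != major]
        if rest:
            minor, minor_count = max(rest, key=lambda bn: (bn[1], -ord(bn[0])))
            freq = minor_count / total
            if freq >= allele_threshold:
                allelic.append((pos, major, minor, min(freq, 0.5)))
    if ambiguous_columns:
        raise AmbiguousConsensusError(ambiguous_columns)

    return GermlineReference(
        sequence="".join(consensus),
        allelic_positions=allelic,
        frame_offset=frame_offset,
        source="inferred",
    )


@dataclass
class Subgroup:
    haplotype: tuple  # bases at allelic positions, in position order
    reference: GermlineReference
    clones: list


@dataclass
class SubgroupPartition:
    groups: dict  # haplotype key -> Subgroup
    unresolved: list  # clones equidistant from two haplotypes

    def __iter__(self):
        return iter(self.groups.values())


def split_subgroups(clones: Sequence, germline: GermlineReference,
                    min_support: int = 2) -> SubgroupPartition:
    """Partition clones by their haplotype at the germline's allelic positions.

    Candidate haplotypes are the major/minor combinations observed exactly in
    at least ``min_support`` clones (so a lone PCR-jumping hybrid cannot
    legitimize its own recombinant haplotype; if no combination reaches the
    cutoff every observed combination is admitted).  Each clone goes to the
    candidate with the fewest mismatches at allelic positions only;
    equidistant clones are flagged unresolved and excluded.  Each subgroup
    gets its own reference with the haplotype bases substituted in (allelic
    positions retained so they stay excluded from mutation counts).
    """
    clones = list(clones)
    positions = [p for p, *_ in germline.allelic_positions]
    if not positions:
        key = "all"
        ref = GermlineReference(
            sequence=germline.sequence, allelic_positions=[],
            frame_offset=germline.frame_offset, source=germline.source)
        return SubgroupPartition(groups={key: Subgroup((), ref, clones)}, unresolved=[])

    allowed = {p: {major, minor} for p, major, minor, _ in germline.allelic_positions}

    def bases_at(clone):
        return tuple(clone.sequence[p] if p < len(clone.sequence) else "N" for p in positions)

    combo_counts: dict = {}
    for clone in clones:
        hap = bases_at(clone)
        if all(b in allowed[p] for p, b in zip(positions, hap)):
            combo_counts[hap] = combo_counts.get(hap, 0) + 1
    candidates = [hap for hap, n in combo_counts.items() if n >= min_support]
    if not candidates:
        candidates = list(combo_counts)
    if not candidates:
        candidates = [tuple(major for _, major, _, _ in germline.allelic_positions)]

    groups = {}
    unresolved = []
    for clone in clones:
        hap = bases_at(clone)
        dists = [sum(a != b for a, b in zip(hap, cand)) for cand in candidates]
        best = min(dists)
        if dists.count(best) > 1:
            unresolved.append(clone)
            continue
        chosen = candidates[dists.index(best)]
        key = "-".join(f"{p}{b}" for p, b in zip(positions, chosen))
        if key not in groups:
            seq = list(germline.sequence)
            for p, b in zip(positions, chosen):
                seq[p] = b
            ref = GermlineReference(
                sequence="".join(seq),
                allelic_positions=list(germline.allelic_positions),
                frame_offset=germline.frame_offset,
                source=germline.source,
            )
            groups[key] = Subgroup(haplotype=chosen, reference=ref, clones=[])
        groups[key].clones.append(clone)
    return SubgroupPartition(groups=groups, unresolved=unresolved)


def read_allotype_profiles(path) -> list:
    """Read allotype profiles from TSV rows ``allotype_id<TAB>position_1based
    <TAB>base`` (header optional); positions are converted to 0-based."""
    by_id: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("allotype_id"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            allotype_id, pos_1based, base = parts
            by_id.setdefault(allotype_id, []).append((int(pos_1based) - 1, base))
    return [AllotypeProfile(aid, positions) for aid, positions in by_id.items()]


def genotype_calls_frame(calls: Sequence):
    """Genotype calls as a TSV-ready DataFrame."""
    import pandas as pd

    rows = []
    for c in calls:
        rows.append({
            "individual": c.individual_id,
            "allele_1": c.alleles[0] if c.alleles else "",
            "allele_2": c.alleles[1] if len(c.alleles) > 1 else "",
            "support": ";".join(f"{a}={n}" for a, n in sorted(c.support.items())),
            "unassigned": c.unassigned,
            "novel_candidates": ";".join(c.novel_candidates),
            "warnings": ";".join(c.warnings),
        })
    return pd.DataFrame(rows)


def genotype_allotypes(individual_id: str, constant_sequences: Sequence,
                       profiles: Sequence, chimera_tolerance: float = 0.95,
                       max_mismatch: int = 1) -> GenotypeCall:
    """Call an individual's allotype pair from its constant-region sequences.

    Each sequence is assigned to the profile with the fewest diagnostic-
    position mismatches (ties -> unassigned; more than ``max_mismatch``
    mismatches -> novel-allotype candidate).  The genotype is homozygous when
    one profile explains at least ``chimera_tolerance`` of assignable clones,
    otherwise the two best-supported profiles.
    """
    ids = {p.allotype_id for p in profiles}
    if len(ids) != len(list(profiles)):
        raise ValueError("duplicate allotype ids in profile set")

    support: Counter = Counter()
    unassigned = 0
    novel = []
    for idx, seq in enumerate(constant_sequences):
        sequence = seq.sequence if hasattr(seq, "sequence") else str(seq)
        scores = [(p.mismatches(sequence), p.allotype_id) for p in profiles]
        best = min(s for s, _ in scores)
        winners = [a for s, a in scores if s == best]
        if best > max_mismatch:
            novel.append(getattr(seq, "clone_id", f"seq{idx}"))
        elif len(winners) > 1:
            unassigned += 1
        else:
            support[winners[0]] += 1

    warnings = []
    assignable = sum(support.values())
    if assignable == 0:
        return GenotypeCall(individual_id, alleles=(), support={},
                            unassigned=unassigned, novel_candidates=novel,
                            warnings=["no assignable clones"])
    ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    if assignable < 2:
        warnings.append("low support: genotype called from a single clone")
    if len(ranked) == 1 or ranked[0][1] / assignable >= chimera_tolerance:
        alleles = (ranked[0][0], ranked[0][0])
    else:
        alleles = tuple(sorted((ranked[0][0], ranked[1][0])))
    return GenotypeCall(individual_id, alleles=alleles, support=dict(support),
                        unassigned=unassigned, novel_candidates=novel,
                        warnings=warnings)


def flag_chimeras(clone, allele_refs) -> str:
    """Classify a clone as a PCR-jumping chimera between two allele references.

    The verdict is ``"chimera"`` iff the clone's bases at the diagnostic
    positions (where the two alleles differ) form one 5' run matching allele 1
    followed by one 3' run matching allele 2 (or vice versa), each run
    covering at least two diagnostic sites — the single-crossover signature of
    template switching.  Fewer than four diagnostic positions ->
    ``"untestable"``; interleaved patterns are treated as mutations
    (``"not_chimera"``).
    """
    ref_a, ref_b = allele_refs
    seq_a = ref_a.sequence if hasattr(ref_a, "sequence") else str(ref_a)
    seq_b = ref_b.sequence if hasattr(ref_b, "sequence") else str(ref_b)
    if len(seq_a) != len(seq_b):
        raise ValueError("allele references must have equal length")
    diagnostics = [i for i, (a, b) in enumerate(zip(seq_a, seq_b)) if a != b]
    if len(diagnostics) < 4:
        return "untestable"
    sequence = clone.sequence if hasattr(clone, "sequence") else str(clone)
    labels = []
    for pos in diagnostics:
        if pos >= len(sequence):
            continue
        if sequence[pos] == seq_a[pos]:
            labels.append("A")
        elif sequence[pos] == seq_b[pos]:
            labels.append("B")
    if len(labels) < 4:
        return "untestable"
    for split in range(2, len(labels) - 1):
        left, right = labels[:split], labels[split:]
        if len(set(left)) == 1 and len(set(right)) == 1 and left[0] != right[0]:
            return "chimera"
    return "not_chimera"


def cluster_v_families(v_sequences: Sequence, identity_threshold: float = 0.75) -> list:
    """Single-linkage clustering of V sequences on pairwise global-alignment
    nucleotide identity.  Returns one integer family label per input sequence;
    families are numbered 1..n by size (descending), ties by first occurrence.
    """
    seqs = [s.sequence if hasattr(s, "sequence") else str(s) for s in v_sequences]
    n = len(seqs)
    if n == 0:
        return []
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for i in range(n):
        for j in range(i + 1, n):
            if pairwise_identity(seqs[i], seqs[j]) >= identity_threshold:
                union(i, j)

    members: dict = {}
    for i in range(n):
        members.setdefault(find(i), []).append(i)
    ordered = sorted(members.values(), key=lambda m: (-len(m), m[0]))
    labels = [0] * n
    for family_number, group in enumerate(ordered, start=1):
        for i in group:
            labels[i] = family_number
    return labels


@dataclass
class JAssignment:
    j_id: Optional[str]
    score: int
    matches: int
    offset: int  # clone coordinate of the best J placement (-1 if unassigned)


def assign_j_segment(clone, j_library: Sequence, v_end: int = 0,
                     min_match_fraction: float = 0.8) -> JAssignment:
    """Best-scoring ungapped placement of each library J 3' of the V region.

    Score = matches - mismatches over the full J length at the best offset;
    ties go to the lower library index (and leftmost offset within a J).  The
    clone is unassigned when the best J has fewer than
    ``min_match_fraction * len(J)`` matching bases.
    """
    if not j_library:
        raise ValueError("J library is empty")
    sequence = (clone.sequence if hasattr(clone, "sequence") else str(clone))[v_end:]
    best = JAssignment(j_id=None, score=-(10 ** 9), matches=0, offset=-1)
    for j_id, j_seq in j_library:
        jlen = len(j_seq)
        if jlen == 0 or jlen > len(sequence):
            continue
        for off in range(len(sequence) - jlen + 1):
            matches = sum(1 for a, b in zip(sequence[off:off + jlen], j_seq) if a == b)
            score = 2 * matches - jlen
            if score > best.score:
                best = JAssignment(j_id=j_id, score=score, matches=matches,
                                   offset=off + v_end)
    if best.j_id is not None:
        j_len = dict(j_library)[best.j_id]
        if best.matches < min_match_fraction * len(j_len):
            return JAssignment(j_id=None, score=best.score, matches=best.matches, offset=-1)
    return best
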