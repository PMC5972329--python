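"""Truth-tagged synthetic repertoire generator.

Emulates the data-generating process the analysis assumes: clones are built
by V-J-C assembly with junctional trimming/addition, then mutated site-by-
site with independent Bernoulli hazards

    hazard(site) = mutation_rate x base_bias(germline base)
                   x motif_multiplier (if the site is a motif-mutable position)

substitutions are transitions with probability ``transition_prob`` (else
uniform over the two transversions), and rare 1-nt indels model frameshifts.
Heterozygous individuals carry two constant-region allotypes mixed at
``allele_ratio``.  Every planted event is recorded in a truth table so that
each pipeline stage has a parameter-recovery test.  Defaults mirror the
clone-library scale the analysis targets: 79 clones, a 336 nt constant
region, 1.76 substitutions per 1,000 bp, 93% transitions, ~0.05 frameshifts
per clone.  There is no lineage or clonal-burst structure: the statistics
under test are marginal counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from shmprof._util import TRANSITION_PARTNER
from shmprof.motifs import MOTIF_PATTERNS, scan_motifs
from shmprof.seqio import CloneRecord, RegionMap

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


def _default_bias():
    return {b: 1.0 for b in _BASES}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_clones: int = 79
    v_length: int = 300          # nt, kept a multiple of 3
    c_length: int = 336          # 112 codons of constant region
    composition: tuple = (0.25, 0.25, 0.25, 0.25)  # A, C, G, T weights
    j_library_size: int = 20
    j_length: int = 51
    junction_indel_range: int = 3    # max nt trimmed from V/J and max inserted
    mutation_rate: float = 1.76e-3   # substitutions per bp
    base_bias: dict = field(default_factory=_default_bias)
    transition_prob: float = 0.93
    motif_multipliers: dict = field(default_factory=dict)  # motif class -> rate multiplier
    indel_rate: float = 0.05         # frameshift indel events per clone
    heterozygous: bool = False
    diagnostic_positions: tuple = ()  # constant-region offsets distinguishing allotype B
    allele_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.mutation_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.transition_prob <= 1.0:
            raise ValueError("transition_prob must be in [0,1]")
        if not 0.0 < self.allele_ratio < 1.0:
            raise ValueError("allele_ratio must be in (0,1)")
        if any(m < 0 for m in self.motif_multipliers.values()):
            raise ValueError("motif multipliers must be >= 0")
        if any(b < 0 for b in self.base_bias.values()):
            raise ValueError("base biases must be >= 0")
        unknown = set(self.motif_multipliers) - set(MOTIF_PATTERNS)
        if unknown:
            raise ValueError(f"unknown motif classes: {sorted(unknown)}")
        if sum(self.composition) <= 0:
            raise ValueError("composition weights must not all be zero")


@dataclass
class TruthRecord:
    clone_id: str
    allele: str
    j_id: str
    premutation: str      # the clone's own pre-mutation sequence
    mutations: list       # (position, from_base, to_base, motif_classes)
    indels: list          # (position, +len/-len, sequence)


@dataclass
class References:
    v: str
    j_library: list       # (j_id, sequence)
    c_alleles: list       # one or two allotype sequences
    region_map: RegionMap
    diagnostic_positions: list  # constant-region offsets where alleles differ


@dataclass
class SimulationResult:
    clones: list          # CloneRecord
    truths: list          # TruthRecord
    references: References
    config: SimulationConfig


def _random_codons(rng, n_codons: int, weights) -> str:
    """Random coding sequence with no in-frame stop codons."""
    probs = np.asarray(weights, dtype=float)
    probs = probs / probs.sum()
    out = []
    while len(out) < n_codons:
        codon = "".join(rng.choice(list(_BASES), size=3, p=probs))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def make_reference(config: SimulationConfig) -> References:
    """Build germline V, a J library and the constant-region allotype(s).

    The V and C references are stop-free in frame 0; every J carries an
    FGXG-encoding core so downstream J assignment and J scanning have a
    realistic target.  Allotype B is allotype A with a transition substituted
    at each diagnostic position.  Deterministic under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    v = _random_codons(rng, config.v_length // 3, config.composition)
    core = "TTTGGTTCTGGT"  # encodes F G S G
    j_library = []
    j_codons = max(5, config.j_length // 3)
    for i in range(1, config.j_library_size + 1):
        j = _random_codons(rng, j_codons, config.composition)
        mid = (len(j) // 2) // 3 * 3
        j = j[:mid] + core + j[mid + len(core):]
        j_library.append((f"J{i:02d}", j))
    c_a = _random_codons(rng, config.c_length // 3, config.composition)
    c_alleles = [c_a]
    diagnostics = list(config.diagnostic_positions)
    if config.heterozygous:
        if not diagnostics:
            diagnostics = sorted(rng.choice(config.c_length, size=3, replace=False).tolist())
        c_b = list(c_a)
        for pos in diagnostics:
            c_b[pos] = TRANSITION_PARTNER[c_b[pos]]
        c_alleles.append("".join(c_b))

    v_len = len(v)
    j_len = len(j_library[0][1])
    c_len = len(c_a)
    cuts = [int(v_len * f) for f in (0.20, 0.28, 0.45, 0.55)]
    c0 = v_len + j_len
    region_map = RegionMap(regions=[
        ("FR1", 0, cuts[0]), ("CDR1", cuts[0], cuts[1]),
        ("FR2", cuts[1], cuts[2]), ("CDR2", cuts[2], cuts[3]),
        ("FR3", cuts[3], v_len), ("CDR3", v_len, v_len + 12),
        ("FR4", v_len + 12, v_len + j_len),
        ("C-Ig", c0, c0 + int(c_len * 0.55)),
        ("C-CP", c0 + int(c_len * 0.55), c0 + int(c_len * 0.70)),
        ("C-TM", c0 + int(c_len * 0.70), c0 + int(c_len * 0.90)),
        ("C-CYT", c0 + int(c_len * 0.90), c0 + c_len),
    ], frame_offset=0)
    return References(v=v, j_library=j_library, c_alleles=c_alleles,
                      region_map=region_map, diagnostic_positions=diagnostics)


def _motif_site_multipliers(sequence: str, multipliers: dict) -> dict:
    """Per-position hazard multiplier from motif-mutable positions (product
    over classes hitting the same site); also returns class sets per site."""
    site_mult: dict = {}
    site_classes: dict = {}
    active = [cls for cls, m in multipliers.items() if m != 1.0]
    if not active:
        return {}, {}
    for hit in scan_motifs(sequence, classes=active):
        m = multipliers[hit.motif_class]
        site_mult[hit.mutable_position] = site_mult.get(hit.mutable_position, 1.0) * m
        site_classes.setdefault(hit.mutable_position, set()).add(hit.motif_class)
    return site_mult, site_classes


def simulate_repertoire(config: SimulationConfig,
                        references: Optional[References] = None) -> SimulationResult:
    """Generate a clone set plus per-clone ground truth.

    Fully deterministic under the config seed (identical sequences and truth
    tables across runs).  Raises if any per-site hazard exceeds 1.
    """
    refs = references or make_reference(config)
    rng = np.random.default_rng(config.seed + 1)  # independent of reference stream
    transversions = {b: [x for x in _BASES if x != b and x != TRANSITION_PARTNER[b]]
                     for b in _BASES}
    clones, truths = [], []
    allele_labels = ["A", "B"]
    for idx in range(1, config.n_clones + 1):
        clone_id = f"sim{idx:04d}"
        if config.heterozygous and len(refs.c_alleles) == 2:
            allele = 0 if rng.random() < config.allele_ratio else 1
        else:
            allele = 0
        j_idx = int(rng.integers(0, len(refs.j_library)))
        j_id, j_seq = refs.j_library[j_idx]
        r = config.junction_indel_range
        trim_v = int(rng.integers(0, r + 1)) if r else 0
        trim_j = int(rng.integers(0, r + 1)) if r else 0
        n_ins = int(rng.integers(0, r + 1)) if r else 0
        insert = "".join(rng.choice(list(_BASES), size=n_ins)) if n_ins else ""
        premut = (refs.v[:len(refs.v) - trim_v] + insert + j_seq[trim_j:]
                  + refs.c_alleles[allele])
        L = len(premut)

        arr = np.frombuffer(premut.encode(), dtype=np.uint8)
        hazard = np.empty(L, dtype=float)
        for base in _BASES:
            hazard[arr == ord(base)] = config.mutation_rate * config.base_bias[base]
        site_mult, site_classes = _motif_site_multipliers(premut, config.motif_multipliers)
        for pos, m in site_mult.items():
            hazard[pos] *= m
        if hazard.max(initial=0.0) > 1.0:
            raise ValueError("per-site hazard exceeds 1; rates too high")

        hit_positions = np.nonzero(rng.random(L) < hazard)[0]
        mutated = list(premut)
        mutations = []
        for pos in hit_positions.tolist():
            from_base = premut[pos]
            if rng.random() < config.transition_prob:
                to_base = TRANSITION_PARTNER[from_base]
            else:
                to_base = transversions[from_base][int(rng.integers(0, 2))]
            mutated[pos] = to_base
            mutations.append((pos, from_base, to_base,
                              tuple(sorted(site_classes.get(pos, ())))))

        indels = []
        n_indels = int(rng.poisson(config.indel_rate))
        for _ in range(n_indels):
            pos = int(rng.integers(0, L))
            if rng.random() < 0.5:
                indels.append((pos, -1, premut[pos]))
            else:
                base = _BASES[int(rng.integers(0, 4))]
                indels.append((pos, +1, base))
        # apply right-to-left so recorded positions stay in premutation coords
        for pos, delta, seq_frag in sorted(indels, reverse=True):
            if delta < 0:
                del mutated[pos]
            else:
                mutated.insert(pos, seq_frag)

        clones.append(CloneRecord(clone_id=clone_id, sequence="".join(mutated),
                                  individual_id="sim", tissue="synthetic"))
        truths.append(TruthRecord(
            clone_id=clone_id, allele=allele_labels[allele], j_id=j_id,
            premutation=premut, mutations=mutations, indels=sorted(indels)))
    return SimulationResult(clones=clones, truths=truths, references=refs,
                            config=config)


def truth_compare(called_by_clone: dict, truths: Sequence) -> dict:
    """Precision/recall of substitution calls against the planted truth.

    ``called_by_clone`` maps clone_id to MutationRecord lists with positions
    in the clone's own pre-mutation coordinates.  An event matches on
    (position, from_base, to_base).
    """
    truth_ids = {t.clone_id for t in truths}
    extra = set(called_by_clone) - truth_ids
    if extra:
        raise ValueError(f"called clone ids not in truth set: {sorted(extra)[:5]}")
    tp = fp = fn = 0
    for truth in truths:
        planted = {(p, f, t) for p, f, t, _ in truth.mutations}
        called = {(r.position, r.from_base, r.to_base)
                  for r in called_by_clone.get(truth.clone_id, [])
                  if r.event_class == "substitution"}
        tp += len(planted & called)
        fp += len(called - planted)
        fn += len(planted - called)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return {"true_positives": tp, "false_positives": fp, "false_negatives": fn,
            "precision": precision, "recall": recall}
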