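# Methods

## Setting and model

The package analyses sets of antigen-receptor cDNA clones obtained by
molecular cloning from one individual: each clone is one sequenced molecule,
nearly identical to a shared germline baseline except for somatic point
mutations, occasional indels, junctional (CDR3) variation, and — in
heterozygous individuals — fixed allelic differences.  The statistical model
underlying every stage is marginal: mutations are treated as independent
per-site events, and all inference is on counts (per-nucleotide, per-k-mer,
per-region, per-window).  No lineage or clonal-burst structure is modelled;
clones are assumed independent draws.

The pipeline assumes the clone set is alignable to a *single* reference
end-to-end.  That holds for a restricted PCR on one V gene (plus the shared
constant region), which is the setting the end-to-end `run_pipeline` models.
A pooled library spanning many J segments must be analysed per region (or
with the junction masked): aligning J-diverse clones to one consensus turns
every alternative J into a block of spurious mismatches.  The module
functions (`call_mutations`, `mutability_table`, …) are reference-explicit
precisely so such stratified analyses can be composed.

## Germline and allele inference

The baseline is the column-wise consensus of the clone pool.  Clones of
unequal length are projected onto a scaffold — the first clone of the modal
length, so an indel-bearing outlier cannot impose its coordinate system —
via global alignment.  A column whose second-most-frequent base reaches
`allele_threshold` (default 0.3) of the non-N clones is recorded as
*allelic*: heterozygous positions present as two bases at roughly 50% each,
while somatic hotspots at realistic rates stay far below 30% at pool sizes
of 20–80 clones.  Allelic positions are excluded from all somatic-mutation
counts.  Columns with a three-way tie raise an explicit ambiguity error
rather than guessing.

Subgroups are the major/minor combinations at the allelic positions observed
exactly in at least `min_support` (default 2) clones; requiring support
prevents a lone PCR-jumping hybrid from legitimizing its own recombinant
haplotype.  Clones are assigned by mismatch count at allelic positions only;
equidistant clones are reported unresolved and excluded.  Chimera flagging
uses the single-crossover signature of PCR template switching: one 5′ run of
diagnostic positions matching one allele followed by one 3′ run matching the
other, at least two diagnostic sites per side; fewer than four diagnostic
sites is declared untestable.

## Alignment scoring

`align_clone` uses match +1, mismatch −1, internal gaps −4 for the first
base and −1 per further base.  Terminal gaps are scored linearly at −1 per
base rather than free: when a fragment is aligned without internal gaps, the
total terminal-gap length is fixed by the length difference, so the linear
cost is a placement-independent constant — but it prevents the degenerate
short-overhang alignments that become optimal under fully free end gaps with
a ±1 match/mismatch scheme (where a 1-nt indel between near-identical short
sequences would otherwise be reported as a shifted mismatch).  The traceback
is deterministic (first optimal alignment); near-identical clone/reference
pairs make the event extraction insensitive to the remaining tie-breaks.
Equal-length clone/reference pairs skip alignment entirely (vectorised
column compare) — exact, since no indel is possible, and what keeps
hundred-replicate recovery runs cheap.

## Mutation calling and classification

One record per substitution column and per contiguous gap run.  Positions
where clone or reference has N, masked (primer-covered) spans, and allelic
positions never yield events.  Substitution effects are computed by
translating the germline codon with only that substitution applied (other
positions germline) under the standard genetic code; substitutions creating
a stop are nonsense; substitutions downstream of a frameshift are still
called at the nucleotide level with effect `noncoding`.  Indels are
frameshifts iff their length is not a multiple of 3; frameshifts count
toward total events but never toward Ti/Tv or R/S.  When one codon carries
several substitutions each is classified independently against the germline
codon — per-event bookkeeping that matches published count tables; the
brute-force full-translation classification agrees whenever a codon carries
at most one substitution (property-tested).

Frequencies are events per 1,000 *surveyed* bases: aligned reference
positions summed over clones, excluding masked spans and N columns.
Printed frequencies and ratios are truncated toward zero at two decimals
(full precision retained internally) — the convention of the published
tables this format mirrors, where 10 events / 5,690 bp prints as 1.75.
Rate contrasts between clone sets use the conditional binomial test: given
the total event count, events fall in the target set with probability
proportional to its surveyed bases under equal rates.

## Mutability indices

`MI(x) = observed(x) / expected(x)` with `expected(x) = f(x) · N`, where
`f(x)` is the k-mer's relative frequency among unmasked windows of the
germline and `N` the total attributable observations at that k, so
`Σ expected = Σ observed` by construction.  Attribution of a mutation at
position i: the mononucleotide at i; the dinucleotide starting at i (the one
ending at i for the last position) — a single-attribution rule that keeps
the total conserved; the configurable alternative `"both"` credits both
overlapping dinucleotides and doubles the total; the trinucleotide centred
on i, with edge positions excluded.  These attribution conventions are
choices, not field standards, and are stated here prominently because
di/trinucleotide MI values are only comparable under a declared rule.

Significance per k-mer is the two-cell df = 1 chi-square
`(obs−exp)²/exp + ((N−obs)−(N−exp))²/(N−exp)` with flags at α = 0.01 and
0.001; no multiple-testing correction is applied (reports state the number
of tests).  Because `expected` is normalised to the observed total, a
hotspot with per-site hazard multiplier `b` at composition share `f` yields

    MI = b / (f·b + 1 − f)  <  b        (for f > 0)

— e.g. a 2.5× hazard on a base at f ≈ 0.25 produces MI ≈ 1.8, and an
observed MI of 2.5 at f ≈ 0.27 implies b ≈ 5.4.  `hazard_enrichment`
inverts the identity; parameter-recovery tests check the planted multiplier
through this inversion rather than asserting the (unattainable) equality of
MI and multiplier.

## Motif analysis

AID hotspots RGYW (`[AG]G[CT][AT]`, mutable G) and WRCY (`[AT][AG]C[CT]`,
mutable C) — reverse complements of each other — and the polymerase-eta
motifs WA (mutable A) and TW (mutable T).  Scanning is on the supplied
(sense) strand, matching how cDNA clone studies count motifs; a
reverse-strand scan is available.  All overlapping hits are reported and a
position may carry several classes; the mutable-position semantics make the
double counting well defined.  A mutation is *linked* to a class only when
it sits exactly on a mutable position with the matching germline base;
mutations elsewhere in a motif window are tallied separately as in-window
non-mutable.  Densities are hits per 100 unmasked bp.

## J-segment discovery

A candidate J exon is a maximal 36–75 nt window that (i) translates in some
frame through the conserved core FGXG — relaxed by default to `[FW]G.G` to
admit slightly modified cores, with strict `FG.G` available —, (ii) is
immediately preceded by a 12-type recombination signal sequence: nonamer
(consensus `ACAAAAACC`, ≤2 mismatches), spacer 12±1 nt, heptamer (consensus
`CACAGTG`) whose `CAC` prefix is invariant with ≤1 mismatch in the
remainder, and (iii) is immediately followed by a `GT` splice donor.  Both
strands are scanned; overlapping candidates are deduplicated by score
(= heptamer budget left + nonamer budget left + 1 for a strict core), ties
to the leftmost start.  The consensus sequences and mismatch budgets are the
canonical operationalization of "RSS present"; all are configurable, and the
scanner is validated by planting synthetic cassettes into random background
(exact recovery; zero false positives at zero mismatch budget, with the
false-positive rate at the default budget observed, not asserted).

## The simulator: what it emulates and what it does not

`simulate_repertoire` draws, per clone: an allele (Bernoulli
`allele_ratio`), a J segment (uniform), junctional trimming/insertion within
`junction_indel_range`, then per-site independent Bernoulli substitutions
with hazard `mutation_rate × base_bias(base) × motif multiplier` (motif
multipliers apply at motif-mutable positions computed once on the germline —
static targeting, matching how the analysis scans germline motifs; several
classes at one site multiply), transitions with probability
`transition_prob`, and Poisson-count 1-nt indels.  Every planted event is
recorded per clone in pre-mutation coordinates, so calls are checkable
exactly.

Defaults mirror the clone-library scale the pipeline targets: 79 clones, a
300 nt V, 51 nt J segments, a 336 nt (112-codon) constant region, 1.76
substitutions per 1,000 bp with 93% transitions, 0.05 frameshift indels per
clone, junctional variation up to ±3 nt, and a 50/50 allele mixture when
heterozygous.  Base and motif biases default to 1 — bias is the quantity
under test, not a background assumption.

What the simulator does *not* emulate: clonal lineages and shared mutations,
selection (so R/S follows the neutral enumeration expectation of the
reference's codons, computed by brute force in the tests, not an assumed
constant), sequencing/PCR error profiles beyond the flat rate, strand-biased
targeting, and within-motif position preferences.  Passing recovery tests
therefore demonstrates correctness of the counting machinery under the
stated marginal model, not robustness to lineage structure or selection in
real repertoires.

## Problem sizes and numerical conventions

Recovery suites use 200 clones × ~1 kb at 5 substitutions/1,000 bp (about
1,000 events per replicate, enough to bound every mononucleotide MI within
±15% of 1 at ~2.7σ), 100 replicates for the type-I check, 50 kb backgrounds
with 15 planted cassettes for the J scanner, 1,000 random kilobase sequences
for the motif oracle, and 10,000 random single-substitution cases for the
R/S oracle — sizes chosen so each check has clear statistical resolution at
desk scale.  Coordinates are 0-based half-open internally; report columns in
1-based coordinates carry an explicit `_1based` suffix; BED output is
0-based half-open.  All tabular output is deterministic (fixed column order,
LF endings, `%.6g` floats) and every run writes a metadata file from which
the bundle is reproducible.

## Known limitations

- Single-reference assumption of the end-to-end pipeline (see above);
  J-diverse pools need per-region composition or junction masking.
- The allele threshold separates 50/50 alleles from hotspots only for pool
  sizes ≳ 20 clones; below that, binomial noise can push a true allele under
  any fixed threshold.
- Di/trinucleotide MI depends on the attribution convention; cross-study
  comparison requires the same rule.
- The chimera rule detects only single-crossover hybrids; double-crossover
  artifacts are counted as mutations.
- J discovery reflects its configured consensus/budget rules; true segments
  with non-canonical RSS spacing fall outside the default band.
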