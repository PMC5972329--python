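import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shmprof import germline as gl
from shmprof.seqio import CloneRecord
from shmprof.simulate import SimulationConfig, simulate_repertoire

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


def clones_from(seqs):
    return [CloneRecord(f"c{i}", s) for i, s in enumerate(seqs)]


class TestAlignClone:
    def test_identity(self):
        aln = gl.align_clone("ACGT", "ACGT")
        assert aln.score == 4 and aln.substitutions == [] and aln.n_matches == 4

    def test_single_substitution(self):
        aln = gl.align_clone("AGGT", "ACGT")
        assert [(p, a, b) for p, a, b in aln.substitutions] == [(1, "C", "G")]

    def test_single_deletion(self):
        aln = gl.align_clone("ATGAT", "ATGGAT")
        assert len(aln.deletions) == 1
        start, end = aln.deletions[0]
        assert end - start == 1
        assert aln.insertions == [] and aln.substitutions == []

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            gl.align_clone("", "ACGT")

    @settings(max_examples=50, derandomize=True)
    @given(a=dna, b=dna)
    def test_score_symmetric(self, a, b):
        assert gl.align_clone(a, b).score == gl.align_clone(b, a).score


class TestInferGermline:
    def test_fifty_fifty_column_is_allelic(self):
        base = "ACGTACGTGG"
        seqs = [base] * 3 + [base[:4] + "T" + base[5:]] * 3
        ref = gl.infer_germline(clones_from(seqs))
        assert len(ref.allelic_positions) == 1
        pos, major, minor, freq = ref.allelic_positions[0]
        assert pos == 4 and freq == pytest.approx(0.5)
        assert {major, minor} == {"A", "T"}

    def test_rare_variant_is_not_allelic(self):
        base = "ACGTACGTGG"
        seqs = [base] * 5 + [base[:4] + "G" + base[5:]]
        ref = gl.infer_germline(clones_from(seqs))
        assert ref.allelic_positions == []
        assert ref.sequence == base

    @pytest.mark.parametrize("threshold", [0.2, 0.3, 0.45])
    def test_two_subgroup_pool_recovers_two_allelic_positions(self, threshold):
        """An exactly balanced two-haplotype pool yields the two planted
        allelic positions for any threshold up to 0.45."""
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACGT"), size=120))
        variant = list(base)
        variant[40] = {"A": "G", "G": "A", "C": "T", "T": "C"}[variant[40]]
        variant[80] = {"A": "G", "G": "A", "C": "T", "T": "C"}[variant[80]]
        variant = "".join(variant)
        ref = gl.infer_germline(clones_from([base] * 10 + [variant] * 10),
                                allele_threshold=threshold)
        assert sorted(p for p, *_ in ref.allelic_positions) == [40, 80]

    def test_too_few_clones(self):
        with pytest.raises(gl.InsufficientDataError):
            gl.infer_germline(clones_from(["ACGT"] * 3))

    def test_three_way_tie_is_ambiguous(self):
        seqs = ["AAAA", "AAAA", "ACAA", "ACAA", "AGAA", "AGAA"]
        with pytest.raises(gl.AmbiguousConsensusError) as err:
            gl.infer_germline(clones_from(seqs))
        assert err.value.columns == [1]

    def test_mutation_free_homozygous_pool_recovered_exactly(self, basic_sim):
        config = SimulationConfig(seed=5, n_clones=12, junction_indel_range=0,
                                  indel_rate=0.0, mutation_rate=0.0,
                                  j_library_size=1)
        result = simulate_repertoire(config)
        ref = gl.infer_germline(result.clones)
        assert ref.sequence == result.truths[0].premutation
        assert ref.allelic_positions == []

    @pytest.mark.parametrize("threshold", [0.2, 0.3, 0.4])
    def test_planted_alleles_recovered_across_thresholds(self, het_sim, threshold):
        """Binomial allele sampling puts the realized minor fraction near but
        not exactly at 0.5, so thresholds up to 0.4 must still recover the
        planted positions."""
        ref = gl.infer_germline(het_sim.clones, allele_threshold=threshold)
        planted = {len(het_sim.references.v) + len(het_sim.references.j_library[0][1]) + p
                   for p in het_sim.references.diagnostic_positions}
        assert {p for p, *_ in ref.allelic_positions} == planted


class TestSplitSubgroups:
    def _germline(self):
        seq = "A" * 100
        return gl.GermlineReference(
            sequence=seq, allelic_positions=[(10, "A", "T", 0.5), (20, "A", "G", 0.5)])

    def test_assignment_by_allelic_positions_only(self):
        ref = self._germline()
        s = list("A" * 100)
        s[10], s[20] = "T", "G"
        s[50] = "C"  # somatic mutation elsewhere must not affect grouping
        part = gl.split_subgroups(clones_from(["A" * 100, "".join(s)]), ref)
        assert set(part.groups) == {"10A-20A", "10T-20G"}
        assert part.groups["10T-20G"].reference.sequence[10] == "T"

    def test_zero_allelic_positions_single_group(self):
        ref = gl.GermlineReference(sequence="A" * 50)
        part = gl.split_subgroups(clones_from(["A" * 50] * 4), ref)
        assert len(part.groups) == 1 and not part.unresolved

    def test_equidistant_clone_unresolved(self):
        ref = self._germline()
        pure_b = list("A" * 100)
        pure_b[10], pure_b[20] = "T", "G"
        hybrid = list("A" * 100)
        hybrid[20] = "G"  # one mismatch to either supported haplotype
        clones = clones_from(["A" * 100, "A" * 100, "".join(pure_b),
                              "".join(pure_b), "".join(hybrid)])
        part = gl.split_subgroups(clones, ref)
        assert [c.clone_id for c in part.unresolved] == ["c4"]
        assert set(part.groups) == {"10A-20A", "10T-20G"}


class TestGenotypeAllotypes:
    profiles = [
        gl.AllotypeProfile("A", [(2, "A"), (5, "C")]),
        gl.AllotypeProfile("B", [(2, "G"), (5, "C")]),
        gl.AllotypeProfile("F", [(2, "G"), (5, "T")]),
    ]

    def test_heterozygous_split(self):
        seqs = ["TTATTCTT"] * 6 + ["TTGTTCTT"] * 5
        call = gl.genotype_allotypes("B1", seqs, self.profiles)
        assert call.alleles == ("A", "B")

    def test_homozygous(self):
        call = gl.genotype_allotypes("B4", ["TTGTTCTT"] * 8, self.profiles)
        assert call.alleles == ("B", "B")

    def test_single_clone_low_support_warning(self):
        call = gl.genotype_allotypes("BX", ["TTGTTTTT"], self.profiles)
        assert call.alleles == ("F", "F")
        assert any("low support" in w for w in call.warnings)

    def test_profiles_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "profiles.tsv"
        p.write_text("allotype_id\tposition_1based\tbase\n"
                     "A\t3\tA\nA\t6\tC\nB\t3\tG\nB\t6\tC\n")
        profiles = gl.read_allotype_profiles(p)
        assert [(pr.allotype_id, pr.diagnostic_positions) for pr in profiles] == \
               [("A", [(2, "A"), (5, "C")]), ("B", [(2, "G"), (5, "C")])]
        call = gl.genotype_allotypes("B4", ["TTGTTCTT"] * 3, profiles)
        frame = gl.genotype_calls_frame([call])
        assert frame.loc[0, "allele_1"] == "B" and frame.loc[0, "allele_2"] == "B"

    def test_novel_allotype_flagged_not_error(self):
        # mismatches both diagnostic positions of every profile
        call = gl.genotype_allotypes("BZ", ["TTCTTGTT"] + ["TTATTCTT"] * 4,
                                     self.profiles)
        assert call.novel_candidates == ["seq0"]
        assert call.alleles == ("A", "A")


class TestFlagChimeras:
    ref_a = "AAAAAAAAAAAA"
    ref_b = "ATATATATATAA"  # diagnostics at 1,3,5,7,9

    def test_single_crossover_is_chimera(self):
        clone = "ATATAAAAAAAA"  # B,B then A,A,A
        assert gl.flag_chimeras(clone, (self.ref_a, self.ref_b)) == "chimera"

    def test_interleaved_is_not_chimera(self):
        clone = "ATAAATAAATAA"  # B,A,B,A,B pattern
        assert gl.flag_chimeras(clone, (self.ref_a, self.ref_b)) == "not_chimera"

    def test_pure_allele_is_not_chimera(self):
        assert gl.flag_chimeras(self.ref_a, (self.ref_a, self.ref_b)) == "not_chimera"

    def test_few_diagnostics_untestable(self):
        assert gl.flag_chimeras("AAAA", ("AAAA", "ATAA")) == "untestable"


class TestClusterVFamilies:
    def test_identity_thresholding(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=100))
        close = a[:85] + "".join("A" if c != "A" else "C" for c in a[85:])  # ~85% id
        far = "".join(rng.choice(list("ACGT"), size=100))
        labels = gl.cluster_v_families([a, close, far])
        assert labels[0] == labels[1] != labels[2]

    def test_single_linkage_chains(self):
        # a~b and b~c above threshold, a~c below: one family via the chain
        a = "A" * 60 + "C" * 40
        b = "A" * 80 + "C" * 20
        c = "A" * 100
        assert gl.pairwise_identity(a, c) < 0.75 <= gl.pairwise_identity(a, b)
        labels = gl.cluster_v_families([a, b, c])
        assert len(set(labels)) == 1

    def test_permutation_invariant_up_to_renaming(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(5)]
        seqs += [seqs[0][:55] + "AAAAA", seqs[1][:55] + "CCCCC"]
        base = gl.cluster_v_families(seqs)
        order = [3, 0, 6, 2, 5, 1, 4]
        permuted = gl.cluster_v_families([seqs[i] for i in order])
        # same partition structure after mapping back
        groups_base = {}
        for i, lab in enumerate(base):
            groups_base.setdefault(lab, set()).add(i)
        groups_perm = {}
        for j, lab in enumerate(permuted):
            groups_perm.setdefault(lab, set()).add(order[j])
        canon = lambda groups: sorted(tuple(sorted(g)) for g in groups.values())
        assert canon(groups_base) == canon(groups_perm)


class TestAssignJSegment:
    library = [("J01", "TTTGGTTCTGGTACC"), ("J02", "CCCAAATTTGGGCCC")]

    def test_exact_match_scores_full_length(self):
        clone = "ACGTACGT" + self.library[0][1] + "GGG"
        res = gl.assign_j_segment(clone, self.library)
        assert res.j_id == "J01" and res.score == len(self.library[0][1])

    def test_below_threshold_unassigned(self):
        clone = "ACGTACGTACGTACGTACGTACGT"
        res = gl.assign_j_segment(clone, self.library)
        assert res.j_id is None

    def test_tie_prefers_lower_library_index(self):
        lib = [("J01", "AAAA"), ("J02", "AAAA")]
        res = gl.assign_j_segment("GGAAAAGG", lib)
        assert res.j_id == "J01"
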