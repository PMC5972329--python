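import numpy as np
import pytest

from conftest import make_frameshift, make_substitution

from shmprof import mutations as mu
from shmprof.germline import GermlineReference
from shmprof.seqio import CloneRecord, RegionMap
from shmprof._util import truncate


class TestCallMutations:
    @pytest.mark.parametrize("germline,clone,expected", [
        # codon GAT->GGT: Asp->Gly replacement, A->G transition
        ("ATGGAT", "ATGGGT", (4, "A", "G", "transition", "replacement")),
        # codon GAT->GAC: Asp->Asp synonymous
        ("ATGGAT", "ATGGAC", (5, "T", "C", "transition", "synonymous")),
        # codon TGG->TGA: Trp->stop nonsense
        ("ATGTGG", "ATGTGA", (5, "G", "A", "transition", "nonsense")),
    ])
    def test_codon_classification(self, germline, clone, expected):
        ref = GermlineReference(sequence=germline)
        records = mu.call_mutations(CloneRecord("c", clone), ref)
        assert len(records) == 1
        r = records[0]
        assert (r.position, r.from_base, r.to_base, r.titv, r.effect) == expected

    def test_allelic_positions_skipped(self):
        ref = GermlineReference(sequence="ATGGAT",
                                allelic_positions=[(4, "A", "G", 0.5)])
        assert mu.call_mutations(CloneRecord("c", "ATGGGT"), ref) == []

    def test_n_columns_never_yield_events(self):
        ref = GermlineReference(sequence="ATGNAT")
        clone = CloneRecord("c", "ATGGNT")
        positions = [r.position for r in mu.call_mutations(clone, ref)]
        assert positions == []  # N on either side excluded

    def test_deletion_called_as_frameshift(self):
        ref = GermlineReference(sequence="ATGGATCCCTTTAAACCCGGG")
        clone = CloneRecord("c", "ATGGATCCCTTAAACCCGGG")  # 1-nt deletion
        records = mu.call_mutations(clone, ref)
        indels = [r for r in records if r.event_class == "deletion"]
        assert len(indels) == 1 and indels[0].effect == "frameshift"

    def test_substitution_after_frameshift_is_noncoding(self):
        ref = GermlineReference(sequence="ATGGATCCCTTTAAACCCGGGTTT")
        clone = CloneRecord("c", "ATGGTCCCTTTAAACCCGGGTTA")  # del at ~4, sub at end
        records = mu.call_mutations(clone, ref)
        subs = [r for r in records if r.event_class == "substitution"]
        assert subs and all(r.effect == "noncoding" for r in subs)

    def test_masked_span_excluded(self):
        ref = GermlineReference(sequence="ATGGAT")
        records = mu.call_mutations(CloneRecord("c", "ATGGGT"), ref,
                                    masked_spans=[(3, 6)])
        assert records == []

    def test_rs_agrees_with_full_translation_oracle(self, rng):
        """Single-substitution classification equals brute-force translation
        of the full mutant sequence."""
        bases = "ACGT"
        for _ in range(300):
            n_codons = int(rng.integers(4, 10))
            ref_seq = "".join(rng.choice(list(bases), size=3 * n_codons))
            pos = int(rng.integers(0, len(ref_seq)))
            to = rng.choice([b for b in bases if b != ref_seq[pos]])
            mutant = ref_seq[:pos] + to + ref_seq[pos + 1:]
            ref = GermlineReference(sequence=ref_seq)
            records = mu.call_mutations(CloneRecord("c", mutant), ref)
            assert len(records) == 1
            prot_ref = mu.translate(ref_seq)
            prot_mut = mu.translate(mutant)
            codon_index = pos // 3
            if prot_ref == prot_mut:
                expected = "synonymous"
            elif prot_mut[codon_index] == "*":
                expected = "nonsense"
            else:
                expected = "replacement"
            assert records[0].effect == expected


class TestSummarize:
    def test_table_shaped_accounting(self):
        # 6 replacement + 2 silent substitutions (7 Ti, 1 Tv) + 2 frameshifts
        records = []
        titvs = ["transition"] * 7 + ["transversion"]
        effects = ["replacement"] * 6 + ["synonymous"] * 2
        for i, (tv, eff) in enumerate(zip(titvs, effects)):
            from_base, to_base = ("A", "G") if tv == "transition" else ("A", "C")
            records.append(make_substitution(i, from_base, to_base, effect=eff))
        records += [make_frameshift(50), make_frameshift(60)]
        s = mu.summarize(records, n_clones=18, n_bp=5690)
        assert s.n_events == 10
        assert (s.replacement, s.silent, s.transitions, s.transversions,
                s.frameshifts) == (6, 2, 7, 1, 2)
        assert s.replacement + s.silent + s.nonsense + s.frameshifts == s.n_events
        assert s.transitions + s.transversions + s.frameshifts == s.n_events
        assert s.printed()["freq_per_kb"] == 1.75  # 1.7575... truncated

    def test_rs_ratio_truncated_not_rounded(self):
        records = [make_substitution(i, "A", "G", effect="replacement") for i in range(26)]
        records += [make_substitution(100 + i, "A", "G", effect="synonymous") for i in range(14)]
        s = mu.summarize(records, n_clones=79, n_bp=24969)
        assert s.rs_ratio == pytest.approx(26 / 14)
        assert s.printed()["rs_ratio"] == 1.85

    def test_zero_events(self):
        s = mu.summarize([], n_clones=5, n_bp=1000)
        assert s.freq_per_kb == 0.0 and s.rs_ratio is None and s.titv_ratio is None

    def test_zero_bp_rejected(self):
        with pytest.raises(ValueError):
            mu.summarize([], n_clones=1, n_bp=0)


class TestSurveyedBases:
    def test_excludes_masked_and_n(self):
        ref = GermlineReference(sequence="ACGTNACGTA")
        clone = CloneRecord("c", "ACGTAACGTA")
        assert mu.surveyed_bases(clone, ref) == 9  # N column dropped
        assert mu.surveyed_bases(clone, ref, masked_spans=[(0, 2)]) == 7


class TestWindowProfile:
    def test_no_events_all_zero(self):
        df = mu.window_profile([], n_clones=10, length=100, window=20)
        assert (df["frequency"] == 0).all()
        assert df["window_start_1based"].tolist()[:2] == [1, 1] or \
               df["window_start_1based"].min() == 1

    def test_direct_frequency_formula(self):
        records = [make_substitution(5, "A", "G"), make_substitution(7, "A", "G")]
        df = mu.window_profile(records, n_clones=48, length=20, window=20)
        row = df[(df["effect"] == "replacement")].iloc[0]
        assert row["frequency"] == pytest.approx(2 / (20 * 48))

    def test_masked_event_excluded_everywhere(self):
        records = [make_substitution(5, "A", "G")]
        df = mu.window_profile(records, n_clones=10, length=40, window=20,
                               masked_spans=[(0, 9)])
        assert df["count"].sum() == 0

    def test_window_counts_conserve_unmasked_events(self, rng):
        records = [make_substitution(int(p), "A", "G",
                                     effect=rng.choice(["replacement", "synonymous"]))
                   for p in rng.integers(0, 500, size=80)]
        masked = [(100, 140)]
        df = mu.window_profile(records, n_clones=20, length=500, window=20,
                               masked_spans=masked)
        unmasked = sum(1 for r in records if not 100 <= r.position < 140)
        assert df["count"].sum() == unmasked

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            mu.window_profile([], n_clones=1, length=10, window=0)


class TestFunctionalStatus:
    germline = GermlineReference(sequence="ATGGATCCCTTTAAACCCGGGTTTACC")

    def test_identical_clone_in_frame(self):
        assert mu.functional_status(CloneRecord("c", self.germline.sequence),
                                    self.germline) == "in_frame"

    def test_point_stop(self):
        seq = self.germline.sequence
        clone = seq[:12] + "TAA" + seq[15:]
        assert mu.functional_status(CloneRecord("c", clone), self.germline) == "stop_codon"

    def test_one_nt_deletion_frameshift(self):
        seq = self.germline.sequence
        clone = seq[:10] + seq[11:]
        assert mu.functional_status(CloneRecord("c", clone), self.germline) == "frameshift"

    def test_nonfunctional_fraction(self):
        statuses = ["in_frame"] * 45 + ["stop_codon"] + ["frameshift"] * 2
        assert mu.nonfunctional_fraction(statuses) == pytest.approx(0.0625)


class TestCompareRates:
    def _summary(self, events, bp):
        records = [make_substitution(i, "A", "G") for i in range(events)]
        return mu.summarize(records, n_clones=10, n_bp=bp)

    def test_ratio_value(self):
        cmp = mu.compare_rates(self._summary(16, 6952), self._summary(8, 12992))
        assert cmp.ratio == pytest.approx(3.7376, abs=5e-3)

    def test_equal_rates(self):
        cmp = mu.compare_rates(self._summary(5, 1000), self._summary(5, 1000))
        assert cmp.ratio == pytest.approx(1.0)
        assert cmp.p_value == pytest.approx(1.0, abs=0.01)

    def test_zero_control_flagged(self):
        cmp = mu.compare_rates(self._summary(10, 1000), self._summary(0, 1000))
        assert cmp.ratio is None and cmp.flag == "control_rate_zero"

    def test_no_events_anywhere(self):
        cmp = mu.compare_rates(self._summary(0, 1000), self._summary(0, 1000))
        assert cmp.flag == "no_events" and cmp.p_value is None


class TestSpectrum:
    def test_matrix_counts(self):
        records = [make_substitution(0, "G", "A"), make_substitution(1, "G", "T"),
                   make_substitution(2, "G", "T"), make_substitution(3, "A", "G")]
        m = mu.substitution_spectrum(records)
        assert m.loc["G", "T"] == 2 and m.loc["G", "A"] == 1 and m.loc["A", "G"] == 1
        assert m.values.sum() == 4


def test_truncate_printed_convention():
    assert truncate(1.7575, 2) == 1.75
    assert truncate(26 / 14, 2) == 1.85
    assert truncate(2.547, 1) == 2.5
    assert truncate(-1.857, 2) == -1.85
    assert truncate(2.5, 1) == 2.5  # guard against float droop
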