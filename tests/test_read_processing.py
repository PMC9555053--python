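"""Read filtering, merging, alignment, variant calling, error thresholds."""

import numpy as np
import pytest

from operon_dms import read_processing as rp
from operon_dms.core import revcomp

from oracles import local_affine_score, min_count_oracle


def _read(seq, q=30, mate=1, rid="r"):
    return rp.SequencingRead(rid, seq, [q] * len(seq), mate)


class TestDemultiplex:
    MIDS = {"unselected": "ACGTAC", "selected": "TGCAGT"}

    def test_assignment_strips_tag(self):
        reads = [_read("ACGTAC" + "AAAA")]
        bins = rp.demultiplex(reads, self.MIDS)
        assert len(bins["unselected"]) == 1
        assert bins["unselected"][0].sequence == "AAAA"

    def test_unmapped_prefix_goes_unassigned(self):
        bins = rp.demultiplex([_read("GGGGGG" + "AAAA")], self.MIDS)
        assert len(bins["unassigned"]) == 1

    def test_conservation(self):
        reads = [_read("ACGTACAA"), _read("TGCAGTAA"), _read("TTTTTTAA")]
        bins = rp.demultiplex(reads, self.MIDS)
        assert sum(len(b) for b in bins.values()) == len(reads)

    def test_duplicate_tag_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            rp.demultiplex([], {"a": "ACGTAC", "b": "ACGTAC"})


class TestQualityFilter:
    def test_good_read_kept(self):
        assert rp.quality_filter(_read("A" * 80, q=30)) == (True, None)

    def test_short_read_dropped(self):
        keep, reason = rp.quality_filter(_read("A" * 74, q=40))
        assert (keep, reason) == (False, "length")

    def test_low_mean_quality_dropped(self):
        keep, reason = rp.quality_filter(_read("A" * 80, q=19))
        assert (keep, reason) == (False, "quality")

    def test_per_base_mode(self):
        read = rp.SequencingRead("r", "A" * 80, [30] * 79 + [10])
        assert rp.quality_filter(read)[0] is True  # mean still high
        assert rp.quality_filter(read, per_base=True)[0] is False


class TestMergePair:
    def test_identical_full_overlap(self):
        t = "ACGTACGTACGTACGTACGT"
        fwd, rev = _read(t), _read(revcomp(t), mate=2)
        assert rp.merge_pair(fwd, rev) == t

    def test_partial_overlap_concatenates(self):
        t = "ATGCCGTTAACCGGTTGCAGTCAGGAC"  # fwd covers [0:20], rev covers [7:]
        fwd = _read(t[:20])
        rev = _read(revcomp(t[7:]), mate=2)
        assert rp.merge_pair(fwd, rev) == t

    def test_single_mismatch_rejected(self):
        t = "ACGTACGTACGTACGTACGT"
        corrupted = t[:10] + ("A" if t[10] != "A" else "C") + t[11:]
        fwd, rev = _read(t), _read(revcomp(corrupted), mate=2)
        assert rp.merge_pair(fwd, rev) is None

    def test_no_overlap_rejected(self):
        fwd = _read("A" * 15)
        rev = _read("C" * 15, mate=2)  # revcomp G-run never matches A-run
        assert rp.merge_pair(fwd, rev) is None


class TestAlignment:
    def test_identical_read_scores_5L(self):
        ref = "ATGAAACTGTCTGAATGG"
        aln = rp.align_read(ref, ref)
        assert aln.score == 5 * len(ref)

    def test_internal_deletion_detected(self):
        ref = "ATGAAACCCGGGTTTACACTG"
        read = ref[:9] + ref[12:]  # drop one codon
        aln = rp.align_read(read, ref)
        call = rp.call_variant(aln, ref)
        assert call.rejection in (rp.REJECT_INDEL, rp.REJECT_PARTIAL)

    def test_matches_bruteforce_dp_on_random_pairs(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(8, 31)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(8, 31)))
            aln = rp.align_read(a, b)
            assert aln.score == pytest.approx(local_affine_score(b, a))

    def test_score_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=20))
            b = "".join(rng.choice(list("ACGT"), size=25))
            score = rp.align_read(a, b).score
            assert 0 <= score <= 5 * min(len(a), len(b))


class TestCallVariant:
    REF = "ATGAAACTGTCTGAATGG"

    def test_single_codon_change_called(self):
        read = self.REF[:3] + "CCC" + self.REF[6:]
        call = rp.call_variant(rp.align_read(read, self.REF), self.REF)
        assert call.variant is not None
        assert (call.variant.position, call.variant.mut_codon) == (2, "CCC")

    def test_wt_read(self):
        call = rp.call_variant(rp.align_read(self.REF, self.REF), self.REF)
        assert call.is_wt

    def test_two_codon_changes_rejected(self):
        read = self.REF[:3] + "CCC" + self.REF[6:9] + "GGG" + self.REF[12:]
        call = rp.call_variant(rp.align_read(read, self.REF), self.REF)
        assert call.rejection == rp.REJECT_MULTI

    def test_partial_coverage_rejected(self):
        read = self.REF[: len(self.REF) - 4]  # 90% of gene
        call = rp.call_variant(rp.align_read(read, self.REF), self.REF)
        assert call.rejection == rp.REJECT_PARTIAL

    def test_ambiguous_base_in_mutant_codon_rejected(self):
        read = self.REF[:3] + "CNC" + self.REF[6:]
        call = rp._call_from_equal_length(read, self.REF)
        assert call.rejection == rp.REJECT_AMBIG


class TestTally:
    def test_hand_tally(self):
        from operon_dms.core import Variant

        a = rp.VariantCall(variant=Variant(2, "AAA", "CCC"))
        wt = rp.VariantCall(is_wt=True)
        bad = rp.VariantCall(rejection=rp.REJECT_MULTI)
        calls = [a] * 7 + [wt] * 2 + [bad]
        counts, total, rejects = rp.tally_counts(calls)
        assert counts["p2_AAA>CCC"] == 7
        assert counts["WT"] == 2
        assert total == 9  # rejected read excluded from the total
        assert rejects[rp.REJECT_MULTI] == 1


class TestPhredModel:
    def test_q35_reciprocals(self):
        per_base, per_sub = rp.phred_error_prob(35)
        assert 1 / per_base == pytest.approx(3162, abs=1)
        assert 1 / per_sub == pytest.approx(12649, abs=1)

    def test_simple_values(self):
        assert rp.phred_error_prob(20)[0] == pytest.approx(0.01)
        assert rp.phred_error_prob(0)[0] == pytest.approx(1.0)

    def test_three_alternative_mode(self):
        per_base, per_sub = rp.phred_error_prob(30, n_alternatives=3)
        assert per_sub == pytest.approx(per_base / 3)

    def test_negative_q_rejected(self):
        with pytest.raises(ValueError):
            rp.phred_error_prob(-1)


class TestMinReadsThreshold:
    def test_printed_conventions(self):
        assert rp.min_reads_threshold(100_000, 35, 0.05, "poisson_gt") == 13
        assert rp.min_reads_threshold(100_000, 35, 0.05, "poisson_ge") == 14

    def test_matches_tail_summation_oracle(self):
        for lam in range(1, 21):
            got = rp._poisson_min_count(lam, 0.05, "poisson_gt")
            assert got == min_count_oracle(lam, 0.05, strictly_greater=True)
            got = rp._poisson_min_count(lam, 0.05, "poisson_ge")
            assert got == min_count_oracle(lam, 0.05, strictly_greater=False)

    def test_monotonicity(self):
        ks = [rp.min_reads_threshold(100_000, q) for q in (20, 25, 30, 35, 40)]
        assert ks == sorted(ks, reverse=True)  # non-increasing in q
        ks = [rp.min_reads_threshold(n, 35) for n in (10_000, 50_000, 100_000, 500_000)]
        assert ks == sorted(ks)  # non-decreasing in total reads

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError, match="convention"):
            rp.min_reads_threshold(1000, 35, 0.05, "bogus")


class TestReadConservation:
    def test_every_pair_has_exactly_one_fate(self, toy_spec, tmp_path):
        import numpy as np

        from operon_dms import synthetic_data as sd

        variants = sd.enumerate_nnk_variants(toy_spec)
        lib = sd.library_from_survivals(toy_spec, variants, np.ones(len(variants)))
        cfg = sd.SimConfig(depth_per_replicate=1000, n_replicates=1,
                           sequencing_error_rate=0.02, seed=9)
        table = sd.simulate_counts(lib, cfg)
        (r1, r2), = sd.emit_fastq(lib, table, cfg, str(tmp_path / "e"))
        proc = rp.PairProcessor(toy_spec.coding_sequence, cfg.mid_tags, min_length=10)
        proc.run(r1, r2)
        assert sum(proc.fates.values()) == 2000  # one fate per input pair
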