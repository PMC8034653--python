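"""Read filtering and mutation counting semantics."""

import numpy as np
import pytest
from _oracles import pileup_oracle

from shapebench import (AlignedRead, count_mutations, filter_reads,
                        median_frequency, median_frequency_ratio)
from shapebench.counting import RawRead


def _read(pos, cigar, seq, qual=None, flag=0, name="r"):
    qual = np.full(len(seq), 40, dtype=np.uint8) if qual is None else \
        np.asarray(qual, dtype=np.uint8)
    return AlignedRead(qname=name, flag=flag, rname="ref", pos=pos, mapq=60,
                       cigar=cigar, seq=seq, qual=qual)


class TestFilterReads:
    def test_terminal_ns_trimmed(self):
        kept, stats = filter_reads([RawRead("a", "NNACGUNN", np.full(8, 30))])
        assert kept[0].seq == "ACGU"
        assert stats["bases_trimmed"] == 4

    def test_internal_n_dropped(self):
        kept, stats = filter_reads([RawRead("a", "ACNGU", np.full(5, 30))])
        assert not kept
        assert stats["dropped_internal_n"] == 1

    def test_low_quality_ends_trimmed(self):
        quals = np.array([10, 10, 30, 30, 30, 30])
        kept, stats = filter_reads([RawRead("a", "ACGUAC", quals)], qmin=20)
        assert kept[0].seq == "GUAC"
        assert stats["bases_trimmed"] == 2

    def test_degenerate_read_dropped(self):
        kept, stats = filter_reads([RawRead("a", "NNNN", np.full(4, 30))])
        assert not kept and stats["dropped_empty"] == 1


class TestCountMutations:
    def test_simple_mismatch_frequency(self):
        ref = "ACGUACGUAC"
        reads = [_read(1, [("M", 10)], ref.replace("U", "U")) for _ in range(7)]
        mutated = "ACGUGCGUAC"  # A->G at position 5
        reads += [_read(1, [("M", 10)], mutated) for _ in range(3)]
        prof = count_mutations(reads, ref, min_coverage=1)
        assert prof.counts[4] == 3
        assert prof.coverage[4] == 10
        assert prof.frequency[4] == pytest.approx(0.3)

    def test_ambiguous_deletion_realigned_right(self):
        # deletion anywhere in the A-run of CAAAG is placed on the rightmost A
        ref = "CAAAG"
        read = _read(1, [("M", 2), ("D", 1), ("M", 2)], "CAAG")
        prof = count_mutations([read], ref, min_coverage=1)
        assert list(prof.counts) == [0, 0, 0, 1, 0]
        assert list(prof.coverage) == [1, 1, 1, 1, 1]

    def test_unambiguous_deletion_invariant_to_realignment(self):
        ref = "ACGUACGUAC"
        read = _read(1, [("M", 4), ("D", 1), ("M", 5)], "ACGUCGUAC")
        on = count_mutations([read], ref, realign_deletions=True, min_coverage=1)
        off = count_mutations([read], ref, realign_deletions=False, min_coverage=1)
        assert list(on.counts) == list(off.counts)
        assert on.counts[4] == 1

    def test_insertion_counted_at_three_prime_position(self):
        ref = "ACGUACGU"
        read = _read(1, [("M", 4), ("I", 2), ("M", 4)], "ACGUGGACGU")
        prof = count_mutations([read], ref, min_coverage=1)
        assert prof.counts[4] == 1  # charged to position 5 (1-based)
        assert prof.counts.sum() == 1
        off = count_mutations([read], ref, count_insertions=False, min_coverage=1)
        assert off.counts.sum() == 0

    def test_low_quality_base_not_covered(self):
        ref = "ACGU"
        qual = np.array([40, 5, 40, 40])
        read = _read(1, [("M", 4)], "AGGU", qual=qual)  # mismatch at low-q pos 2
        prof = count_mutations([read], ref, qmin=20, min_coverage=1)
        assert prof.coverage[1] == 0 and prof.counts[1] == 0

    def test_secondary_and_unmapped_excluded(self):
        ref = "ACGU"
        reads = [_read(1, [("M", 4)], "ACGU"),
                 _read(1, [("M", 4)], "ACGU", flag=0x4),
                 _read(1, [("M", 4)], "ACGU", flag=0x100)]
        prof = count_mutations(reads, ref, min_coverage=1)
        assert prof.coverage.max() == 1

    def test_read_past_reference_end_skipped(self):
        ref = "ACGU"
        prof = count_mutations([_read(3, [("M", 4)], "GUAC")], ref, min_coverage=1)
        assert prof.n_skipped_reads == 1
        assert prof.coverage.sum() == 0

    def test_matches_pileup_oracle_on_mixed_fixture(self):
        """Kernel counting equals an independent per-column pileup, on a
        fixture mixing mismatches, multi-base and ambiguous deletions,
        insertions and quality filtering."""
        rng = np.random.default_rng(42)
        # include homopolymer runs so deletion placement is often ambiguous
        ref = ("".join(rng.choice(list("ACGU"), 18)) + "AAAAA"
               + "".join(rng.choice(list("ACGU"), 17)) + "CCCCC"
               + "".join(rng.choice(list("ACGU"), 5)))
        reads = []
        for k in range(100):
            start = int(rng.integers(1, 20))
            ops = []
            seq = []
            rp = start - 1
            while rp < min(len(ref), start - 1 + 25):
                r = rng.random()
                if r < 0.70:
                    seq.append(ref[rp]); ops.append("M"); rp += 1
                elif r < 0.82:
                    seq.append(str(rng.choice(list("ACGU")))); ops.append("M"); rp += 1
                elif r < 0.92 and ops and ops[-1] == "M":
                    dl = int(rng.integers(1, 3))
                    ops.extend("D" * dl); rp += dl
                elif ops and ops[-1] == "M":
                    seq.append(str(rng.choice(list("ACGU")))); ops.append("I")
                else:
                    seq.append(ref[rp]); ops.append("M"); rp += 1
            while ops and ops[-1] != "M":
                if ops[-1] == "I":
                    seq.pop()
                ops.pop()
            if not ops:
                continue
            cigar = []
            for op in ops:
                if cigar and cigar[-1][0] == op:
                    cigar[-1] = (op, cigar[-1][1] + 1)
                else:
                    cigar.append((op, 1))
            qual = rng.choice([12, 30, 40], size=len(seq), p=[0.1, 0.3, 0.6])
            reads.append(_read(start, cigar, "".join(seq), qual=qual, name=f"r{k}"))
        for realign in (True, False):
            prof = count_mutations(reads, ref, realign_deletions=realign,
                                   min_coverage=1)
            exp_counts, exp_cov = pileup_oracle(reads, ref, realign=realign)
            np.testing.assert_array_equal(prof.counts, exp_counts)
            np.testing.assert_array_equal(prof.coverage, exp_cov)


class TestMedianStatistics:
    def test_identical_profiles_give_ratio_one(self, profile_factory):
        p = profile_factory([0.01, 0.02, 0.03, 0.04, 0.05])
        assert median_frequency_ratio(p, p) == pytest.approx(1.0)

    def test_elementwise_doubling_gives_two(self, profile_factory):
        base = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        assert median_frequency_ratio(profile_factory(2 * base),
                                      profile_factory(base)) == pytest.approx(2.0)

    def test_hand_made_profiles_match_brute_force(self, profile_factory):
        fa = np.array([0.011, 0.002, 0.047, 0.008, 0.031, 0.019, 0.005])
        fb = np.array([0.004, 0.001, 0.009, 0.003, 0.012, 0.006, 0.002])
        a, b = profile_factory(fa), profile_factory(fb)
        expected = np.median(fa) / np.median(fb)
        assert median_frequency_ratio(a, b) == pytest.approx(expected, rel=1e-2)

    def test_ratio_of_medians_not_median_of_ratios(self, profile_factory):
        fa = np.array([0.1, 0.2, 0.3])
        fb = np.array([0.3, 0.2, 0.1])
        assert median_frequency_ratio(profile_factory(fa), profile_factory(fb)) \
            == pytest.approx(1.0)  # median-of-ratios would be 1/3, 1, 3 -> 1; use asymmetric case
        fa = np.array([0.1, 0.4, 0.4])
        fb = np.array([0.2, 0.2, 0.8])
        got = median_frequency_ratio(profile_factory(fa), profile_factory(fb))
        assert got == pytest.approx(0.4 / 0.2)

    def test_empty_overlap_errors(self, profile_factory):
        a = profile_factory([0.1, np.nan])
        b = profile_factory([np.nan, 0.1])
        with pytest.raises(ValueError):
            median_frequency_ratio(a, b)

    def test_median_frequency_region(self, profile_factory):
        p = profile_factory([0.1, 0.2, 0.3, 0.4])
        assert median_frequency(p, region=(2, 3)) == pytest.approx(0.25)

    def test_frequency_undefined_below_min_coverage(self, profile_factory):
        p = profile_factory([0.1, 0.2], coverage=50, min_coverage=100)
        assert np.isnan(p.frequency).all()
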