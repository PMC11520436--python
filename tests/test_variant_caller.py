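import math

import pytest

from hhtalign.io_formats import SamRecord
from hhtalign.variant_caller import (CallerConfig, PileupColumn,
                                     build_pileups, call_column, call_indels,
                                     call_region, left_align_indel,
                                     mark_duplicates)


def _record(qname, pos, cigar, seq, qual=None, flag=0, mapq=60):
    qual = qual or "I" * len(seq)
    return SamRecord(qname=qname, flag=flag, rname="c", pos=pos, mapq=mapq,
                     cigar=cigar, seq=seq, qual=qual)


class TestMarkDuplicates:
    def test_highest_quality_sum_kept(self):
        a = _record("a", 10, "4M", "ACGT", qual="IIII")      # sum 160
        b = _record("b", 10, "4M", "ACGT", qual="!!!!")      # sum 0
        mark_duplicates([a, b])
        assert not a.is_duplicate
        assert b.is_duplicate

    def test_unique_positions_untouched(self):
        recs = [_record(f"q{i}", 10 * i, "4M", "ACGT") for i in range(5)]
        mark_duplicates(recs)
        assert not any(r.is_duplicate for r in recs)

    def test_k_copies_flag_k_minus_1(self):
        recs = [_record(f"q{i}", 33, "4M", "ACGT") for i in range(4)]
        mark_duplicates(recs)
        assert sum(r.is_duplicate for r in recs) == 3

    def test_soft_clip_aware_grouping(self):
        # same unclipped start despite different POS
        a = _record("a", 10, "4M", "ACGT")
        b = _record("b", 12, "2S2M", "ACGT")
        mark_duplicates([a, b])
        assert sum(r.is_duplicate for r in (a, b)) == 1

    def test_strand_separates_groups(self):
        a = _record("a", 10, "4M", "ACGT")
        b = _record("b", 10, "4M", "ACGT", flag=16)
        mark_duplicates([a, b])
        assert not a.is_duplicate and not b.is_duplicate


class TestBuildPileups:
    REF = "ACGTACGTACGTACGT"

    def _columns(self, records, **kw):
        return list(build_pileups(records, "c", self.REF, **kw))

    def test_single_read_columns(self):
        cols = self._columns([_record("r", 7, "5M", "TACGT")])
        assert [c.pos for c in cols] == [7, 8, 9, 10, 11]
        assert all(c.depth == 1 for c in cols)

    def test_deletion_marker(self):
        cols = self._columns([_record("r", 0, "2M1D2M", "ACTA")])
        by_pos = {c.pos: c for c in cols}
        assert by_pos[2].observations[0][0] == "*"
        assert by_pos[3].observations[0][0] == "T"

    def test_insertion_attaches_to_previous_column(self):
        cols = self._columns([_record("r", 4, "2M2I2M", "ACGGGT")])
        by_pos = {c.pos: c for c in cols}
        assert by_pos[5].insertions == [("GG", "r")]

    def test_overlapping_depth(self):
        records = [_record(f"r{i}", 2, "6M", "GTACGT") for i in range(30)]
        cols = self._columns(records)
        assert all(c.depth == 30 for c in cols)

    def test_soft_clips_contribute_nothing(self):
        cols = self._columns([_record("r", 3, "2S3M1S", "GGTACA")])
        assert [c.pos for c in cols] == [3, 4, 5]

    def test_duplicates_and_low_mapq_excluded(self):
        dup = _record("d", 0, "4M", "ACGT", flag=0x400)
        low = _record("l", 0, "4M", "ACGT", mapq=3)
        cols = self._columns([dup, low])
        assert cols == []

    def test_bad_cigar_rejected_and_counted(self):
        bad = _record("x", 0, "10M", "ACGT")
        rejected = []
        cols = self._columns([bad], rejected=rejected)
        assert cols == []
        assert rejected == ["x"]

    def test_span_limits_columns(self):
        cols = self._columns([_record("r", 0, "10M", "ACGTACGTAC")],
                             span=(3, 6))
        assert [c.pos for c in cols] == [3, 4, 5]


def _column(ref_base, obs):
    col = PileupColumn("c", 0, ref_base)
    for i, (base, q) in enumerate(obs):
        col.observations.append((base, q, "+", f"r{i}"))
    return col


class TestCallColumn:
    def test_hom_alt_10_of_10(self):
        call = call_column(_column("A", [("G", 30)] * 10))
        assert call is not None
        assert call.genotype == "hom"
        assert call.alt == "G"
        assert call.qual >= 20

    def test_all_ref_no_call(self):
        assert call_column(_column("A", [("A", 30)] * 10)) is None

    def test_het_5_of_10(self):
        call = call_column(_column("A", [("A", 30)] * 5 + [("G", 30)] * 5))
        assert call is not None
        assert call.genotype == "het"
        assert call.ref_depth == 5 and call.alt_depth == 5

    def test_below_min_depth_no_call(self):
        assert call_column(_column("A", [("G", 30)] * 3)) is None

    def test_low_quality_bases_ignored(self):
        config = CallerConfig(min_baseq=10)
        col = _column("A", [("G", 5)] * 10)       # all below the floor
        assert call_column(col, config) is None

    def test_low_fraction_alt_below_qual_threshold(self):
        # 8 ref / 2 alt at Q15: QUAL = -10 log10 P(hom-ref | data) ~ 10,
        # under the default threshold of 20 -> no call
        assert call_column(_column("A", [("A", 15)] * 8 + [("G", 15)] * 2)) \
            is None


class TestLeftAlignIndel:
    def test_deletion_in_homopolymer_shifts_left(self):
        #        0123456789
        bases = "GCAAAAT"
        # deleting one A at the run's end == deleting the first A
        pos, ref, alt = left_align_indel(bases, 5, "AA"[0] + "A", "A")
        assert (pos, ref, alt) == (1, "CA", "C")

    def test_insertion_in_repeat_shifts_left(self):
        bases = "GACACACT"
        pos, ref, alt = left_align_indel(bases, 6, "C", "CAC")
        assert (pos, ref, alt) == (0, "G", "GAC")

    def test_non_repetitive_unmoved(self):
        bases = "GATTC"
        assert left_align_indel(bases, 2, "T", "TG") == (2, "T", "TG")

    def test_snp_unmoved(self):
        assert left_align_indel("ACGT", 2, "G", "T") == (2, "G", "T")


class TestIndelCalls:
    REF = "ACGTAGGTCATGCATCCATGGATCCTAG"

    def test_hom_insertion_called(self):
        # all 30 reads carry +AC after position 9
        records = [_record(f"r{i}", 4, "6M2I8M", "AGGTCAACTGCATCCA")
                   for i in range(30)]
        cols = list(build_pileups(records, "c", self.REF))
        calls = call_indels(cols, self.REF, "c")
        assert len(calls) == 1
        call = calls[0]
        assert call.genotype == "hom"
        assert len(call.alt) - len(call.ref) == 2

    def test_single_stray_deletion_not_called(self):
        clean = [_record(f"c{i}", 4, "14M", "AGGTCATGCATCCA")
                 for i in range(29)]
        stray = [_record("s", 4, "6M1D7M", "AGGTCATGCATCC")]
        cols = list(build_pileups(clean + stray, "c", self.REF))
        assert call_indels(cols, self.REF, "c") == []

    def test_het_deletion_at_half_of_reads(self):
        with_del = [_record(f"d{i}", 4, "6M2D6M", "AGGTCACATCCA")
                    for i in range(15)]
        without = [_record(f"w{i}", 4, "14M", "AGGTCATGCATCCA")
                   for i in range(15)]
        cols = list(build_pileups(with_del + without, "c", self.REF))
        calls = call_indels(cols, self.REF, "c")
        assert len(calls) == 1
        call = calls[0]
        assert call.genotype == "het"
        assert len(call.ref) - len(call.alt) == 2


class TestCallRegion:
    REF = "ACGTAGGTCATGCATCCATGGATCCTAG"

    def test_duplicates_do_not_change_calls(self):
        base = [_record(f"r{i}", 2 + (i % 3), "10M",
                        self.REF[2 + (i % 3):12 + (i % 3)].replace("G", "G"))
                for i in range(12)]
        # introduce a SNP supported by all reads at position 9 (C->T)
        reads = []
        for i in range(12):
            start = 2 + (i % 3)
            seq = list(self.REF[start:start + 10])
            seq[9 - start] = "T"
            reads.append(_record(f"r{i}", start, "10M", "".join(seq)))
        calls_plain = call_region(list(reads), "c", self.REF)
        dups = [_record(f"{r.qname}_dup", r.pos, r.cigar, r.seq)
                for r in reads[:6]]
        calls_dup = call_region(list(reads) + dups, "c", self.REF)
        assert [(c.pos, c.ref, c.alt, c.genotype) for c in calls_plain] == \
            [(c.pos, c.ref, c.alt, c.genotype) for c in calls_dup]

    def test_region_split_invariance(self):
        reads = []
        for i in range(20):
            start = i % 6
            seq = list(self.REF[start:start + 14])
            seq[10 - start] = "A"       # SNP at position 10 (T->A)
            reads.append(_record(f"r{i}", start, "14M", "".join(seq)))
        whole = call_region(list(reads), "c", self.REF)
        left = call_region(list(reads), "c", self.REF, span=(0, 8))
        right = call_region(list(reads), "c", self.REF,
                            span=(8, len(self.REF)))
        assert [(c.pos, c.ref, c.alt) for c in whole] == \
            [(c.pos, c.ref, c.alt) for c in left + right]
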