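"""Sub-alignment collection, filtering and signal extraction."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from invcall.alignment_scan import (
    FORWARD,
    LEFT,
    NAHR,
    NHEJ,
    REVERSE,
    RIGHT,
    InversionSignal,
    ScanConfig,
    SubAlignment,
    collect_subalignments,
    extract_signals,
    filter_subalignments,
    sort_signals,
)

CFG = ScanConfig()


def sub(read_id="r1", chrom="chr21", ref=(1000, 2000), read=(0, 1000), strand=FORWARD, mapq=60):
    return SubAlignment(
        read_id=read_id,
        chrom=chrom,
        ref_start=ref[0],
        ref_end=ref[1],
        read_start=read[0],
        read_end=read[1],
        strand=strand,
        mapq=mapq,
    )


class TestCollect:
    def test_primary_plus_supplementary_retained(self, bam_factory):
        path = bam_factory(
            [
                {"name": "r1", "pos": 1000, "cigar": "1000M1000S"},
                {"name": "r1", "pos": 5000, "cigar": "1000S1000M", "flag": 0x800 | 0x10},
            ]
        )
        out = collect_subalignments(path)
        assert set(out) == {"r1"}
        assert len(out["r1"]) == 2

    def test_uniquely_aligned_read_excluded(self, bam_factory):
        path = bam_factory([{"name": "solo", "pos": 1000, "cigar": "2000M"}])
        assert collect_subalignments(path) == {}

    def test_cross_chromosome_pair_excluded(self, bam_factory):
        path = bam_factory(
            [
                {"name": "r1", "chrom": "chr21", "pos": 1000, "cigar": "1000M1000S"},
                {"name": "r1", "chrom": "chr22", "pos": 1000, "cigar": "1000S1000M", "flag": 0x800},
            ],
            contigs={"chr21": 100_000, "chr22": 100_000},
        )
        assert collect_subalignments(path) == {}

    def test_sa_tag_and_supplementary_deduplicated(self, bam_factory):
        # the same split is described both by a supplementary record and the
        # primary's SA tag; it must be counted once
        path = bam_factory(
            [
                {
                    "name": "r1",
                    "pos": 1000,
                    "cigar": "1000M1000S",
                    "tags": [("SA", "chr21,5001,-,1000S1000M,60,0;")],
                },
                {
                    "name": "r1",
                    "pos": 5000,
                    "cigar": "1000S1000M",
                    "flag": 0x800 | 0x10,
                    "tags": [("SA", "chr21,1001,+,1000M1000S,60,0;")],
                },
            ]
        )
        out = collect_subalignments(path)
        assert len(out["r1"]) == 2

    def test_secondary_ignored(self, bam_factory):
        path = bam_factory(
            [
                {"name": "r1", "pos": 1000, "cigar": "1000M1000S"},
                {"name": "r1", "pos": 9000, "cigar": "1000M1000S", "flag": 0x100},
            ]
        )
        assert collect_subalignments(path) == {}

    def test_reverse_strand_read_coordinates_mirrored(self, bam_factory):
        # reverse alignment with leading soft clip 300, aligned 700:
        # original-read coords are [0, 700) (clips mirrored)
        path = bam_factory(
            [
                {"name": "r1", "pos": 1000, "cigar": "300S700M", "flag": 0x10},
                {"name": "r1", "pos": 5000, "cigar": "700S300M"},
            ]
        )
        subs = {s.strand: s for s in collect_subalignments(path)["r1"]}
        assert (subs[REVERSE].read_start, subs[REVERSE].read_end) == (0, 700)
        assert (subs[FORWARD].read_start, subs[FORWARD].read_end) == (700, 1000)


class TestFilter:
    def test_short_subalignment_removed(self):
        a = sub(read=(0, 400), ref=(1000, 1400))
        b = sub(read=(300, 4000), ref=(2000, 5700))
        assert filter_subalignments([a, b], CFG) == [b]

    def test_contained_interval_removed(self):
        a = sub(read=(0, 3000), ref=(1000, 4000))
        b = sub(read=(500, 2500), ref=(6000, 8000))
        assert filter_subalignments([a, b], CFG) == [a]

    def test_single_interval_unchanged(self):
        a = sub(read=(0, 600), ref=(1000, 1600))
        assert filter_subalignments([a], CFG) == [a]

    def test_equal_intervals_keep_higher_mapq(self):
        a = sub(read=(0, 1000), mapq=10)
        b = sub(read=(0, 1000), ref=(5000, 6000), mapq=50)
        assert filter_subalignments([a, b], CFG) == [b]

    def test_mapq_filter(self):
        a = sub(read=(0, 1000), mapq=5)
        assert filter_subalignments([a], ScanConfig(min_mapq=10)) == []
        assert filter_subalignments([a], CFG) == [a]

    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.integers(400, 4000), st.integers(0, 60)),
            max_size=8,
        )
    )
    def test_idempotent(self, raw):
        alns = [
            sub(read=(s, s + l), ref=(10 * s + 1, 10 * s + l + 1), mapq=q)
            for s, l, q in raw
        ]
        once = filter_subalignments(alns, CFG)
        assert filter_subalignments(once, CFG) == once


class TestExtractSignals:
    def test_left_breakpoint_forward_signal(self):
        a = sub(read=(0, 3000), ref=(10_000, 13_000), strand=FORWARD)
        b = sub(read=(3000, 6500), ref=(6000, 9500), strand=REVERSE)
        (sig,) = extract_signals([a, b], CFG)
        assert (sig.side, sig.strand, sig.mechanism) == (LEFT, FORWARD, NHEJ)
        # forward-first signals estimate breakpoints from reference ends
        assert (sig.ref_start, sig.ref_end) == (9500, 13_000)

    def test_read_overlap_above_threshold_is_nahr(self):
        a = sub(read=(0, 3000), ref=(10_000, 13_000), strand=FORWARD)
        b = sub(read=(2400, 6000), ref=(6000, 9600), strand=REVERSE)
        (sig,) = extract_signals([a, b], CFG)
        assert sig.mechanism == NAHR
        assert sig.ir_overlap == 600

    def test_overlap_at_threshold_is_nhej(self):
        a = sub(read=(0, 3000), ref=(10_000, 13_000), strand=FORWARD)
        b = sub(read=(2600, 6000), ref=(6000, 9400), strand=REVERSE)
        (sig,) = extract_signals([a, b], CFG)
        assert sig.ir_overlap == 400
        assert sig.mechanism == NHEJ

    def test_same_orientation_pair_ignored(self):
        a = sub(read=(0, 3000), ref=(10_000, 13_000))
        b = sub(read=(3000, 6000), ref=(20_000, 23_000))
        assert extract_signals([a, b], CFG) == []

    def test_cross_chromosome_pair_ignored(self):
        a = sub(read=(0, 3000), ref=(10_000, 13_000), strand=FORWARD)
        b = sub(read=(3000, 6000), ref=(6000, 9000), strand=REVERSE, chrom="chr22")
        assert extract_signals([a, b], CFG) == []

    def test_reverse_first_signal_uses_reference_starts(self):
        a = sub(read=(0, 3000), ref=(9500, 12_500), strand=REVERSE)
        b = sub(read=(3000, 6000), ref=(13_000, 16_000), strand=FORWARD)
        (sig,) = extract_signals([a, b], CFG)
        assert (sig.side, sig.strand) == (RIGHT, REVERSE)
        assert (sig.ref_start, sig.ref_end) == (9500, 13_000)

    def test_three_subalignments_yield_two_signals(self):
        # forward read spanning an inversion [10000, 14000): the middle piece
        # aligns in reverse; both junction pairs emit a signal, covering both
        # strand classes, and both signals estimate the same breakpoints
        a = sub(read=(0, 2000), ref=(8000, 10_000), strand=FORWARD)
        b = sub(read=(2000, 6000), ref=(10_000, 14_000), strand=REVERSE)
        c = sub(read=(6000, 8000), ref=(14_000, 16_000), strand=FORWARD)
        sigs = extract_signals([a, b, c], CFG)
        assert len(sigs) == 2
        assert {s.strand for s in sigs} == {FORWARD, REVERSE}
        assert {(s.ref_start, s.ref_end) for s in sigs} == {(10_000, 14_000)}

    def test_emitted_signal_sources_opposite_strand_same_chrom(self):
        # property over a bag of pairs: only opposite-strand same-chrom pairs emit
        alns = [
            sub(read=(i * 1000, (i + 1) * 1000), ref=(1000 * i + 1, 1000 * i + 900),
                strand=FORWARD if i % 3 else REVERSE)
            for i in range(6)
        ]
        for sig in extract_signals(alns, CFG):
            assert sig.chrom == "chr21"


class TestSortSignals:
    def _sig(self, chrom, start):
        return InversionSignal(
            read_id="r", chrom=chrom, ref_start=start, ref_end=start + 100,
            side=LEFT, strand=FORWARD, mechanism=NHEJ, ir_overlap=0,
        )

    def test_sorted_by_chrom_then_start(self):
        sigs = [self._sig("chr2", 500), self._sig("chr1", 900)]
        assert [(s.chrom, s.ref_start) for s in sort_signals(sigs)] == [
            ("chr1", 900),
            ("chr2", 500),
        ]

    def test_empty(self):
        assert sort_signals([]) == []

    def test_same_chrom_by_start(self):
        sigs = [self._sig("chr1", 100), self._sig("chr1", 50)]
        assert [s.ref_start for s in sort_signals(sigs)] == [50, 100]
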