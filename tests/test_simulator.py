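"""Simulated genomes, reads and idealized split alignments."""

import numpy as np
import pysam
import pytest

from invcall.alignment_scan import FORWARD, REVERSE, ScanConfig, collect_subalignments, extract_signals, filter_subalignments
from invcall.clustering import IRPair
from invcall.simulator import (
    SimConfig,
    SimRead,
    TruthRecord,
    apply_inversions,
    idealized_split_align,
    revcomp,
    sample_reads,
    simulate_reference_with_irs,
    simulate_to_bam,
)

SCAN = ScanConfig()


def small_cfg(**kw):
    base = dict(
        ref_length=400_000, n_nahr=1, n_nhej_short=1, n_nhej_long=1,
        nahr_size_range=(20_000, 30_000), nhej_long_range=(4_000, 20_000),
        locus_margin=25_000, coverage=5.0, mean_read_len=6000, seed=11,
    )
    base.update(kw)
    return SimConfig(**base)


def perfect_read(name, hap, start, end, is_reverse, haplotypes):
    n = end - start
    return SimRead(
        name=name, hap=hap, hap_start=start, hap_end=end, is_reverse=is_reverse,
        ops=np.zeros(n, dtype=np.uint8), ins=np.zeros(n, dtype=bool),
        seq=haplotypes[hap][start:end].copy(),
    )


class TestGenome:
    def test_planted_ir_is_reverse_complement(self):
        cfg = small_cfg()
        ref, irs, loci = simulate_reference_with_irs(cfg)
        (ir,) = irs
        left = ref[ir.left_start : ir.left_end]
        right = ref[ir.right_start : ir.right_end]
        assert np.array_equal(right, revcomp(left))

    def test_divergence_reduces_identity(self):
        cfg = small_cfg(ir_divergence=0.05, ir_length_range=(2000, 3000))
        ref, irs, _ = simulate_reference_with_irs(cfg)
        (ir,) = irs
        left = ref[ir.left_start : ir.left_end]
        right = ref[ir.right_start : ir.right_end]
        identity = np.mean(right == revcomp(left))
        assert 0.92 <= identity <= 0.98

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="cannot place"):
            simulate_reference_with_irs(small_cfg(ref_length=50_000))


class TestApplyInversions:
    def truth(self, start, end, genotype, het_hap=0):
        return TruthRecord(chrom="sim1", start=start, end=end, mechanism="NHEJ",
                           genotype=genotype, het_hap=het_hap)

    def test_hom_flips_both_haplotypes(self):
        ref = np.random.default_rng(0).integers(0, 4, 10_000, dtype=np.uint8)
        t = self.truth(2000, 5000, "invinv")
        h0, h1 = apply_inversions(ref, [t])
        for h in (h0, h1):
            assert np.array_equal(h[2000:5000], revcomp(ref[2000:5000]))
            assert np.array_equal(h[:2000], ref[:2000])

    def test_het_flips_exactly_one_haplotype(self):
        ref = np.random.default_rng(0).integers(0, 4, 10_000, dtype=np.uint8)
        t = self.truth(2000, 5000, "refinv", het_hap=1)
        h0, h1 = apply_inversions(ref, [t])
        assert np.array_equal(h0, ref)
        assert np.array_equal(h1[2000:5000], revcomp(ref[2000:5000]))

    def test_haplotype_length_conserved(self):
        ref = np.random.default_rng(0).integers(0, 4, 10_000, dtype=np.uint8)
        h0, h1 = apply_inversions(ref, [self.truth(2000, 5000, "invinv")])
        assert len(h0) == len(h1) == len(ref)

    def test_reverse_complement_is_involution(self):
        ref = np.random.default_rng(1).integers(0, 4, 5000, dtype=np.uint8)
        assert np.array_equal(revcomp(revcomp(ref)), ref)
        t = self.truth(1000, 3000, "invinv")
        h0, _ = apply_inversions(ref, [t])
        back, _ = apply_inversions(h0, [t])
        assert np.array_equal(back, ref)

    def test_overlapping_truth_rejected(self):
        ref = np.zeros(10_000, dtype=np.uint8)
        with pytest.raises(ValueError, match="overlapping"):
            apply_inversions(ref, [self.truth(2000, 5000, "invinv"),
                                   self.truth(4000, 7000, "invinv")])


class TestSampleReads:
    def test_error_free_reads_are_exact_substrings(self):
        cfg = small_cfg(err_sub=0.0, err_ins=0.0, err_del=0.0, coverage=0.5)
        ref = np.random.default_rng(2).integers(0, 4, 100_000, dtype=np.uint8)
        for read in sample_reads((ref, ref), cfg):
            assert np.array_equal(read.seq, ref[read.hap_start : read.hap_end])

    def test_mean_read_length_matches_config(self):
        cfg = small_cfg(coverage=30.0, mean_read_len=6000)
        ref = np.random.default_rng(3).integers(0, 4, 200_000, dtype=np.uint8)
        lengths = [len(r.seq) for r in sample_reads((ref, ref), cfg)]
        mean = np.mean(lengths)
        se = np.std(lengths) / np.sqrt(len(lengths))
        assert abs(mean - 6000) < 3 * se + 200  # truncation shifts the mean slightly

    def test_total_bases_near_coverage_target(self):
        cfg = small_cfg(coverage=10.0)
        ref = np.random.default_rng(4).integers(0, 4, 200_000, dtype=np.uint8)
        total = sum(len(r.seq) for r in sample_reads((ref, ref), cfg))
        assert abs(total - 10.0 * 200_000) / (10.0 * 200_000) < 0.05


def scan_signals(bam_path):
    out = {}
    for read_id, alns in collect_subalignments(bam_path).items():
        out[read_id] = extract_signals(filter_subalignments(alns, SCAN), SCAN)
    return out


@pytest.fixture(scope="module")
def nahr_setup(tmp_path_factory):
    cfg = small_cfg(n_nhej_short=0, n_nhej_long=0, ir_length_range=(600, 600),
                    nahr_size_range=(30_000, 30_000), endpoint_jitter=0)
    rng = np.random.default_rng(cfg.seed)
    ref, irs, loci = simulate_reference_with_irs(cfg, rng)
    truth = TruthRecord(chrom=cfg.chrom, start=loci[0].start, end=loci[0].end,
                        mechanism="NAHR", genotype="invinv", ir=irs[0])
    haps = apply_inversions(ref, [truth])
    return cfg, ref, truth, haps, tmp_path_factory.mktemp("nahr")


class TestIdealizedSplitAlign:
    def _align(self, reads, truth, cfg, path):
        idealized_split_align(reads, [truth], cfg, str(path))
        return str(path)

    def test_left_junction_read_has_ir_overlap(self, nahr_setup):
        cfg, ref, truth, haps, tmp = nahr_setup
        x = truth.start
        read = perfect_read("r0", 0, x - 4000, x + 4000, False, haps)
        bam = self._align([read], truth, cfg, tmp / "left.bam")
        subs = collect_subalignments(bam)["r0"]
        assert len(subs) == 2
        assert {s.strand for s in subs} == {FORWARD, REVERSE}
        a, b = sorted(subs, key=lambda s: s.read_start)
        overlap = a.read_end - b.read_start
        assert abs(overlap - 600) <= 2  # read overlap ~ IR length
        (sig,) = extract_signals(filter_subalignments(subs, SCAN), SCAN)
        assert sig.mechanism == "NAHR"
        # breakpoint estimates sit at the IR outer edges
        assert abs(sig.ref_start - truth.ir.left_end) <= 1
        assert abs(sig.ref_end - truth.ir.right_end) <= 1

    def test_read_inside_inversion_aligns_reverse_unsplit(self, nahr_setup):
        cfg, ref, truth, haps, tmp = nahr_setup
        mid = (truth.start + truth.end) // 2
        read = perfect_read("r0", 0, mid - 3000, mid + 3000, False, haps)
        bam = self._align([read], truth, cfg, tmp / "inside.bam")
        with pysam.AlignmentFile(bam) as fh:
            recs = list(fh.fetch(until_eof=True))
        assert len(recs) == 1
        assert recs[0].is_reverse

    def test_read_crossing_both_junctions_yields_two_signals(self, nahr_setup):
        cfg, ref, truth, haps, tmp = nahr_setup
        read = perfect_read("r0", 0, truth.start - 3000, truth.end + 3000, False, haps)
        bam = self._align([read], truth, cfg, tmp / "both.bam")
        sigs = scan_signals(bam)["r0"]
        assert len(sigs) == 2
        assert {s.strand for s in sigs} == {FORWARD, REVERSE}

    def test_read_reversal_flips_side_keeps_strand_and_breakpoints(self, nahr_setup):
        cfg, ref, truth, haps, tmp = nahr_setup
        x = truth.start
        fwd = perfect_read("r0", 0, x - 4000, x + 4000, False, haps)
        rev = perfect_read("r0", 0, x - 4000, x + 4000, True, haps)
        bam_f = self._align([fwd], truth, cfg, tmp / "f.bam")
        bam_r = self._align([rev], truth, cfg, tmp / "r.bam")
        (sf,) = scan_signals(bam_f)["r0"]
        (sr,) = scan_signals(bam_r)["r0"]
        assert (sf.ref_start, sf.ref_end) == (sr.ref_start, sr.ref_end)
        assert sf.strand == sr.strand
        assert sf.side != sr.side

    def test_emitted_alignments_match_reference(self, nahr_setup):
        # '=' operations in the emitted records must agree with the reference,
        # including inside IR extension zones
        cfg, ref, truth, haps, tmp = nahr_setup
        x = truth.start
        rng = np.random.default_rng(5)
        reads = list(sample_reads((haps[0], haps[1]),
                                  small_cfg(coverage=0.3, seed=9), rng))
        bam = self._align(reads, truth, cfg, tmp / "check.bam")
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        ref_str = bases[ref].tobytes().decode()
        checked = 0
        with pysam.AlignmentFile(bam) as fh:
            for rec in fh.fetch(until_eof=True):
                seq = rec.query_sequence
                qpos = 0
                rpos = rec.reference_start
                for op, n in rec.cigartuples:
                    if op == 7:  # '=' must match the reference exactly
                        assert seq[qpos : qpos + n] == ref_str[rpos : rpos + n]
                        checked += n
                    if op in (0, 7, 8):
                        qpos += n
                        rpos += n
                    elif op in (1, 4):
                        qpos += n
                    elif op in (2, 3):
                        rpos += n
        assert checked > 10_000


class TestDeterminism:
    def test_same_seed_reproduces_run(self, tmp_path):
        cfg = small_cfg()
        a = simulate_to_bam(cfg, str(tmp_path / "a"))
        b = simulate_to_bam(cfg, str(tmp_path / "b"))
        assert [(t.start, t.end, t.genotype) for t in a.truth] == [
            (t.start, t.end, t.genotype) for t in b.truth
        ]
        with pysam.AlignmentFile(a.bam_path) as fa, pysam.AlignmentFile(b.bam_path) as fb:
            for ra, rb in zip(fa.fetch(until_eof=True), fb.fetch(until_eof=True)):
                assert ra.to_string() == rb.to_string()
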