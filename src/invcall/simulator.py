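"""Hermetic diploid inversion simulator with an idealized split-aligner.

The simulator emulates the study design used to benchmark long-read
inversion callers: a random reference carrying planted NAHR inversions
(flanked by inverted-repeat pairs, second copy the reverse complement of
the first) and NHEJ inversions; a diploid pair of haplotypes with each
inversion applied to one (heterozygous) or both (homozygous) copies; long
reads with an exponential length distribution sequenced from both strands
with independent per-base substitution, insertion and deletion errors; and
the split alignments such reads produce at inversion breakpoints.

Instead of running an external aligner, the known read origin is converted
directly into the sub-alignments its layout implies: the orientation flips
inside the inversion, and at NAHR junctions each sub-alignment is extended
through the homologous half of the flanking inverted repeat, so that the
adjacent sub-alignments overlap on the read by approximately the IR length.
Alignments are emitted with extended (=/X) CIGAR operations that are exact
with respect to the reference, sorted, and indexed.

NAHR note: with identical inverted repeats the inverted interval is only
defined up to the crossover position inside the repeat.  The simulator
flips and records the canonical midpoint representative (IR midpoint to IR
midpoint), which is also the expected value of a breakpoint estimate that
averages left- and right-junction signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .clustering import IRPair

logger = logging.getLogger(__name__)

NAHR = "NAHR"
NHEJ = "NHEJ"
HET = "refinv"
HOM = "invinv"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# trace op codes (per haplotype position)
_OP_MATCH, _OP_SUB, _OP_DEL = 0, 1, 2
# pysam cigar codes
_C_INS, _C_DEL, _C_SOFT, _C_EQ, _C_X = 1, 2, 4, 7, 8


@dataclass(frozen=True)
class TruthRecord:
    """A simulated inversion: [start, end) is the flipped interval
    (for NAHR the canonical IR-midpoint representative)."""

    chrom: str
    start: int
    end: int
    mechanism: str  # NAHR or NHEJ
    genotype: str  # HET ("refinv") or HOM ("invinv")
    ir: Optional[IRPair] = None
    het_hap: int = 0  # haplotype carrying the inversion when heterozygous

    def __post_init__(self) -> None:
        if self.end - self.start < 1000:
            raise ValueError("simulated inversions must be at least 1 kb")
        if self.mechanism == NAHR and self.ir is None:
            raise ValueError("NAHR truth records must reference an IR pair")


@dataclass
class SimConfig:
    ref_length: int = 5_000_000
    chrom: str = "sim1"
    n_nahr: int = 10
    n_nhej_short: int = 5
    n_nhej_long: int = 5
    nahr_size_range: Tuple[int, int] = (20_000, 80_000)
    nhej_short_range: Tuple[int, int] = (1_000, 4_000)
    nhej_long_range: Tuple[int, int] = (4_000, 100_000)
    ir_length_range: Tuple[int, int] = (500, 3_000)
    ir_divergence: float = 0.0
    mean_read_len: int = 9_000
    min_read_len: int = 300
    coverage: float = 20.0
    err_sub: float = 0.051
    err_ins: float = 0.049
    err_del: float = 0.078
    endpoint_jitter: int = 20
    locus_margin: int = 30_000
    min_piece_len: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.err_sub, self.err_ins, self.err_del):
            if not 0.0 <= r < 1.0:
                raise ValueError("error rates must lie in [0, 1)")
        if self.ir_length_range[0] < 500:
            raise ValueError("planted IRs must be at least 500 bp")


@dataclass
class _Locus:
    kind: str  # NAHR or NHEJ
    start: int = 0  # flip interval (filled at placement)
    end: int = 0
    ir_len: int = 0  # NAHR only
    block: int = 0  # reference span consumed, incl. IRs for NAHR

    @property
    def a1(self) -> int:  # left IR start (NAHR)
        return self.start - self.ir_len // 2

    @property
    def b1(self) -> int:
        return self.a1 + self.ir_len

    @property
    def b2(self) -> int:  # right IR end (NAHR)
        return self.end + self.ir_len - (self.ir_len - self.ir_len // 2)  # == a2 + ir_len

    @property
    def a2(self) -> int:
        return self.end - (self.ir_len - self.ir_len // 2)


@dataclass
class SimRead:
    name: str
    hap: int
    hap_start: int
    hap_end: int
    is_reverse: bool  # sequenced orientation relative to the haplotype
    ops: np.ndarray  # per-haplotype-base trace (match/sub/del)
    ins: np.ndarray  # single-base insertion after each kept base
    seq: np.ndarray  # read bases in haplotype orientation (uint8 codes)


def revcomp(seq: np.ndarray) -> np.ndarray:
    """Reverse complement of a base-code array (A=0, C=1, G=2, T=3)."""
    return (3 - seq)[::-1]


def _plan_loci(cfg: SimConfig, rng: np.random.Generator) -> List[_Locus]:
    loci: List[_Locus] = []
    for _ in range(cfg.n_nahr):
        m = int(rng.integers(cfg.ir_length_range[0], cfg.ir_length_range[1] + 1))
        size = int(rng.integers(cfg.nahr_size_range[0], cfg.nahr_size_range[1] + 1))
        loci.append(_Locus(kind=NAHR, ir_len=m, block=size + m, end=size))
    for _ in range(cfg.n_nhej_short):
        size = int(rng.integers(cfg.nhej_short_range[0], cfg.nhej_short_range[1] + 1))
        loci.append(_Locus(kind=NHEJ, block=size, end=size))
    for _ in range(cfg.n_nhej_long):
        lo, hi = cfg.nhej_long_range
        size = int(round(10 ** rng.uniform(np.log10(lo), np.log10(hi))))
        loci.append(_Locus(kind=NHEJ, block=size, end=size))
    loci = [loci[i] for i in rng.permutation(len(loci))]
    total = sum(l.block for l in loci) + (len(loci) + 1) * cfg.locus_margin
    if total > cfg.ref_length:
        raise ValueError(
            f"cannot place loci: need {total} bp (blocks + margins) "
            f"but reference is {cfg.ref_length} bp"
        )
    extra = cfg.ref_length - total
    bonus = rng.multinomial(extra, np.full(len(loci) + 1, 1.0 / (len(loci) + 1)))
    pos = 0
    for i, locus in enumerate(loci):
        pos += cfg.locus_margin + int(bonus[i])
        size = locus.end  # temporary: flip-interval length stored in .end
        if locus.kind == NAHR:
            a1 = pos
            h = locus.ir_len // 2
            locus.start = a1 + h
            locus.end = locus.start + size  # midpoint-to-midpoint
        else:
            locus.start = pos
            locus.end = pos + size
        pos += locus.block
    return loci


def simulate_reference_with_irs(
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    loci: Optional[List[_Locus]] = None,
) -> Tuple[np.ndarray, List[IRPair], List[_Locus]]:
    """Random reference with planted inverted-repeat pairs.

    Returns (sequence as uint8 codes, IR pairs, placed loci).  The second
    repeat copy is the reverse complement of the first, mutated at rate
    ``cfg.ir_divergence``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if loci is None:
        loci = _plan_loci(cfg, rng)
    ref = rng.integers(0, 4, cfg.ref_length, dtype=np.uint8)
    ir_pairs: List[IRPair] = []
    for locus in loci:
        if locus.kind != NAHR:
            continue
        copy = revcomp(ref[locus.a1 : locus.b1])
        if cfg.ir_divergence > 0:
            mut = rng.random(len(copy)) < cfg.ir_divergence
            copy = copy.copy()
            copy[mut] = (copy[mut] + rng.integers(1, 4, int(mut.sum()))) % 4
        ref[locus.a2 : locus.b2] = copy
        ir_pairs.append(
            IRPair(
                chrom=cfg.chrom,
                left_start=locus.a1,
                left_end=locus.b1,
                right_start=locus.a2,
                right_end=locus.b2,
                identity=1.0 - cfg.ir_divergence,
            )
        )
    return ref, ir_pairs, loci


def assign_genotypes(
    loci: Sequence[_Locus],
    cfg: SimConfig,
    rng: np.random.Generator,
    ir_pairs: Optional[Sequence[IRPair]] = None,
) -> List[TruthRecord]:
    """Bernoulli(0.5) heterozygous/homozygous genotypes for planted loci."""
    ir_by_start = {p.left_start: p for p in (ir_pairs or [])}
    out = []
    for locus in loci:
        gt = HET if rng.random() < 0.5 else HOM
        out.append(
            TruthRecord(
                chrom=cfg.chrom,
                start=locus.start,
                end=locus.end,
                mechanism=locus.kind,
                genotype=gt,
                ir=ir_by_start.get(locus.a1) if locus.kind == NAHR else None,
                het_hap=int(rng.integers(0, 2)),
            )
        )
    return out


def apply_inversions(
    reference: np.ndarray, truth: Sequence[TruthRecord]
) -> Tuple[np.ndarray, np.ndarray]:
    """Diploid haplotypes: each truth interval reverse-complemented on one
    haplotype (het) or both (hom).  Truth records must not overlap."""
    ordered = sorted(truth, key=lambda t: t.start)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start < prev.end:
            raise ValueError(
                f"overlapping truth records {prev.start}-{prev.end} and {nxt.start}-{nxt.end}"
            )
    haps = [reference.copy(), reference.copy()]
    for t in ordered:
        targets = [t.het_hap] if t.genotype == HET else [0, 1]
        for h in targets:
            haps[h][t.start : t.end] = revcomp(haps[h][t.start : t.end])
    return haps[0], haps[1]


def _flips_for_hap(truth: Sequence[TruthRecord], hap: int) -> List[TruthRecord]:
    return sorted(
        (t for t in truth if t.genotype == HOM or t.het_hap == hap),
        key=lambda t: t.start,
    )


def sample_reads(
    haplotypes: Tuple[np.ndarray, np.ndarray],
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Iterator[SimRead]:
    """Sample error-bearing long reads from a diploid genome.

    Read lengths are exponential with mean ``cfg.mean_read_len``; reads come
    from either haplotype and either strand.  The error channel applies, per
    haplotype base, deletion with probability p_del/(1+p_del) and, to kept
    bases, substitution and single-base insertion at the configured rates,
    so that the measured per-aligned-base rates match the configuration.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    d_prime = cfg.err_del / (1.0 + cfg.err_del)
    yield_factor = (1.0 - d_prime) * (1.0 + cfg.err_ins)
    L = len(haplotypes[0])
    target = cfg.coverage * L
    emitted = 0
    idx = 0
    while emitted < target:
        hap = int(rng.integers(0, 2))
        is_rev = bool(rng.random() < 0.5)
        t_len = rng.exponential(cfg.mean_read_len)
        t_len = min(max(t_len, cfg.min_read_len), 0.2 * L)
        n = max(int(round(t_len / yield_factor)), 10)
        if n >= L:
            n = L - 1
        s = int(rng.integers(0, L - n))
        hap_seq = haplotypes[hap]
        dels = rng.random(n) < d_prime
        keep = ~dels
        subs = (rng.random(n) < cfg.err_sub) & keep
        ins = (rng.random(n) < cfg.err_ins) & keep
        base = hap_seq[s : s + n].copy()
        nsub = int(subs.sum())
        if nsub:
            base[subs] = (base[subs] + rng.integers(1, 4, nsub).astype(np.uint8)) % 4
        counts = keep.astype(np.int64) + ins
        prefix = np.concatenate(([0], np.cumsum(counts)))
        read = np.empty(int(prefix[-1]), dtype=np.uint8)
        read[prefix[:-1][keep]] = base[keep]
        nins = int(ins.sum())
        if nins:
            read[prefix[:-1][ins] + 1] = rng.integers(0, 4, nins, dtype=np.uint8)
        ops = np.zeros(n, dtype=np.uint8)
        ops[subs] = _OP_SUB
        ops[dels] = _OP_DEL
        yield SimRead(
            name=f"r{idx:06d}",
            hap=hap,
            hap_start=s,
            hap_end=s + n,
            is_reverse=is_rev,
            ops=ops,
            ins=ins,
            seq=read,
        )
        emitted += len(read)
        idx += 1


@dataclass
class _Piece:
    u: int  # haplotype interval (relative coordinates handled by caller)
    v: int
    flipped: bool
    flip_x: int = 0  # flip interval when flipped
    flip_y: int = 0


def _segment_read(
    read: SimRead, flips: Sequence[TruthRecord], cfg: SimConfig, rng: np.random.Generator
) -> List[_Piece]:
    """Cut a read's haplotype interval at inversion junctions and apply the
    NAHR inverted-repeat extensions and endpoint jitter."""
    s, e = read.hap_start, read.hap_end
    events = [t for t in flips if t.start < e and t.end > s]
    cuts: List[Tuple[int, TruthRecord]] = []
    for t in events:
        if s < t.start < e:
            cuts.append((t.start, t))
        if s < t.end < e:
            cuts.append((t.end, t))
    cuts.sort(key=lambda c: c[0])
    bounds = [s] + [c[0] for c in cuts] + [e]
    pieces: List[_Piece] = []
    jit = lambda: int(rng.integers(0, cfg.endpoint_jitter + 1))
    for lo, hi in zip(bounds, bounds[1:]):
        if hi <= lo:
            continue
        mid = (lo + hi) // 2
        inside = next((t for t in events if t.start <= mid < t.end), None)
        u, v = lo, hi
        if inside is None:
            # identity segment; extend through IR halves at adjacent NAHR junctions
            right_t = next((t for t in events if t.start == hi), None)
            left_t = next((t for t in events if t.end == lo), None)
            if right_t is not None:
                if right_t.mechanism == NAHR:
                    v = min(right_t.ir.left_end, e) - jit()
                else:
                    v = hi - jit()
            if left_t is not None:
                if left_t.mechanism == NAHR:
                    u = max(left_t.ir.right_start, s) + jit()
                else:
                    u = lo + jit()
            pieces.append(_Piece(u=u, v=v, flipped=False))
        else:
            x, y = inside.start, inside.end
            if lo == x:  # read crossed the left junction
                if inside.mechanism == NAHR:
                    u = max(inside.ir.left_start, s) + jit()
                else:
                    u = lo + jit()
            if hi == y:  # read crossed the right junction
                if inside.mechanism == NAHR:
                    h_fwd = inside.ir.right_end - y
                    v = min(y + h_fwd, e) - jit()
                else:
                    v = hi - jit()
            pieces.append(_Piece(u=u, v=v, flipped=True, flip_x=x, flip_y=y))
    return [p for p in pieces if p.v - p.u >= cfg.min_piece_len]


def _rle(arr: np.ndarray) -> List[Tuple[int, int]]:
    if len(arr) == 0:
        return []
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(arr)]))
    return [(int(arr[s]), int(e - s)) for s, e in zip(starts, ends)]


def idealized_split_align(
    reads: Iterable[SimRead],
    truth: Sequence[TruthRecord],
    cfg: SimConfig,
    bam_path: str,
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Emit the split alignments implied by each read's known origin.

    Produces a coordinate-sorted, indexed BAM with extended (=/X) CIGARs,
    one primary record per read (the longest piece) plus supplementary
    records, all carrying SA tags.  Returns the number of records written.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    flips_by_hap = (_flips_for_hap(truth, 0), _flips_for_hap(truth, 1))
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": cfg.chrom, "LN": cfg.ref_length}],
        }
    )
    records = []
    for read in reads:
        pieces = _segment_read(read, flips_by_hap[read.hap], cfg, rng)
        if not pieces:
            continue
        prefix = np.concatenate(
            ([0], np.cumsum((read.ops != _OP_DEL).astype(np.int64) + read.ins))
        )
        total_read_len = int(prefix[-1])
        seq_fwd = _BASES[read.seq].tobytes().decode()
        seq_rev = _BASES[revcomp(read.seq)].tobytes().decode()
        parts = []
        for piece in pieces:
            u, v = piece.u, piece.v
            rel_u, rel_v = u - read.hap_start, v - read.hap_start
            ops = read.ops[rel_u:rel_v]
            # trim leading/trailing deletions so alignments start on a base
            while rel_u < rel_v and ops[0] == _OP_DEL:
                rel_u += 1
                u += 1
                ops = ops[1:]
            while rel_v > rel_u and ops[-1] == _OP_DEL:
                rel_v -= 1
                v -= 1
                ops = ops[:-1]
            if rel_v - rel_u < cfg.min_piece_len:
                continue
            ins = read.ins[rel_u:rel_v]
            r0 = int(prefix[rel_u])
            r1 = int(prefix[rel_v])
            # expanded cigar codes in haplotype order
            base_codes = np.where(
                ops == _OP_DEL, _C_DEL, np.where(ops == _OP_SUB, _C_X, _C_EQ)
            ).astype(np.uint8)
            cum_ins = np.concatenate(([0], np.cumsum(ins)))[:-1]
            idx = np.arange(len(ops)) + cum_ins
            expanded = np.empty(len(ops) + int(ins.sum()), dtype=np.uint8)
            expanded[idx] = base_codes
            if ins.any():
                expanded[idx[ins] + 1] = _C_INS
            # a trailing insertion has no anchor inside the piece: clip it
            while len(expanded) and expanded[-1] == _C_INS:
                expanded = expanded[:-1]
                r1 -= 1
            stored_reverse = piece.flipped
            if stored_reverse:
                expanded = expanded[::-1]
            runs = _rle(expanded)
            if piece.flipped:
                ref_start = piece.flip_x + piece.flip_y - v
                ref_end = piece.flip_x + piece.flip_y - u
            else:
                ref_start, ref_end = u, v
            if not stored_reverse:
                lead, trail = r0, total_read_len - r1
            else:
                lead, trail = total_read_len - r1, r0
            cig = []
            if lead:
                cig.append((_C_SOFT, lead))
            cig.extend(runs)
            if trail:
                cig.append((_C_SOFT, trail))
            nm = sum(n for op, n in runs if op in (_C_X, _C_INS, _C_DEL))
            qlen = r1 - r0
            flag_rev = stored_reverse != read.is_reverse
            parts.append(
                {
                    "ref_start": ref_start,
                    "ref_end": ref_end,
                    "cigar": cig,
                    "reverse": flag_rev,
                    "seq": seq_fwd if not stored_reverse else seq_rev,
                    "nm": nm,
                    "qlen": qlen,
                }
            )
        if not parts:
            continue
        primary = max(range(len(parts)), key=lambda i: parts[i]["qlen"])

        def _sa(p) -> str:
            cigstr = "".join(f"{n}{'MIDNSHP=X'[op]}" for op, n in p["cigar"])
            strand = "-" if p["reverse"] else "+"
            return f"{cfg.chrom},{p['ref_start'] + 1},{strand},{cigstr},60,{p['nm']};"

        for i, p in enumerate(parts):
            a = pysam.AlignedSegment(header)
            a.query_name = read.name
            a.reference_id = 0
            a.reference_start = p["ref_start"]
            a.mapping_quality = 60
            a.cigartuples = p["cigar"]
            a.query_sequence = p["seq"]
            flag = 0
            if p["reverse"]:
                flag |= 0x10
            if i != primary:
                flag |= 0x800
            a.flag = flag
            tags = [("NM", p["nm"])]
            others = "".join(_sa(q) for j, q in enumerate(parts) if j != i)
            if others:
                tags.append(("SA", others))
            a.set_tags(tags)
            records.append(a)
    records.sort(key=lambda a: a.reference_start)
    with pysam.AlignmentFile(bam_path, "wb", header=header) as out:
        for a in records:
            out.write(a)
    pysam.index(bam_path)
    return len(records)


@dataclass
class SimOutput:
    """Artifacts of one hermetic simulation run."""

    cfg: SimConfig
    reference: np.ndarray
    ir_pairs: List[IRPair]
    truth: List[TruthRecord]
    bam_path: str
    n_records: int


def simulate_to_bam(cfg: SimConfig, workdir: str) -> SimOutput:
    """Full simulation: genome, diploid haplotypes, reads, idealized BAM."""
    root = np.random.default_rng(cfg.seed)
    genome_rng, gt_rng, read_rng, align_rng = root.spawn(4)
    ref, ir_pairs, loci = simulate_reference_with_irs(cfg, genome_rng)
    truth = assign_genotypes(loci, cfg, gt_rng, ir_pairs)
    hap0, hap1 = apply_inversions(ref, truth)
    Path(workdir).mkdir(parents=True, exist_ok=True)
    bam_path = str(Path(workdir) / "sim.bam")
    reads = sample_reads((hap0, hap1), cfg, read_rng)
    n = idealized_split_align(reads, truth, cfg, bam_path, align_rng)
    return SimOutput(
        cfg=cfg,
        reference=ref,
        ir_pairs=ir_pairs,
        truth=truth,
        bam_path=bam_path,
        n_records=n,
    )


def reference_to_fasta(reference: np.ndarray, chrom: str, path: str) -> None:
    seq = _BASES[reference].tobytes().decode()
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
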