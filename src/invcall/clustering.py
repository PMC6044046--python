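"""Merging of inversion signals into inversion calls.

Two binning passes are run in sequence.  If an inverted-repeat (IR) database
is supplied, signals whose estimated left and right breakpoints fall within
``X`` bp of an IR pair's left and right repeat intervals are grouped into
that IR's bin and removed.  Remaining signals are grouped by single-linkage
distance binning: a signal joins a bin when both its start and end are less
than ``X`` bp from the bin's running mean start/end.

A bin becomes an inversion call only when it contains supporting reads on
both strands and at both breakpoints, with total support R_inv (one count
per read per side) of at least ``min_support_reads``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .alignment_scan import FORWARD, LEFT, NAHR, REVERSE, RIGHT, InversionSignal


@dataclass(frozen=True)
class IRPair:
    """A pair of inverted repeats: left repeat [left_start, left_end),
    right repeat [right_start, right_end), ordered and non-overlapping."""

    chrom: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.left_end <= self.left_start or self.right_end <= self.right_start:
            raise ValueError("IR repeat intervals must be nonempty")
        if self.left_end > self.right_start:
            raise ValueError("IR repeats must be ordered and non-overlapping")

    @property
    def mean_length(self) -> float:
        return 0.5 * ((self.left_end - self.left_start) + (self.right_end - self.right_start))

    @property
    def gap(self) -> int:
        """Distance between the repeats (inversion size without the IRs)."""
        return self.right_start - self.left_end


@dataclass
class ClusterConfig:
    bin_distance_X: int = 2000
    long_inversion_L: int = 1_000_000
    min_support_reads: int = 3

    def __post_init__(self) -> None:
        if min(self.bin_distance_X, self.long_inversion_L, self.min_support_reads) <= 0:
            raise ValueError("ClusterConfig fields must be positive")


@dataclass
class SignalBin:
    signals: List[InversionSignal] = field(default_factory=list)
    ir: Optional[IRPair] = None
    mean_start: float = 0.0
    mean_end: float = 0.0

    def add(self, sig: InversionSignal) -> None:
        n = len(self.signals)
        self.mean_start = (self.mean_start * n + sig.ref_start) / (n + 1)
        self.mean_end = (self.mean_end * n + sig.ref_end) / (n + 1)
        self.signals.append(sig)


@dataclass
class InversionCall:
    chrom: str
    start: int
    end: int
    left_bp_start: int
    left_bp_end: int
    right_bp_start: int
    right_bp_end: int
    mechanism: str
    ir_overlap: int
    n_left: int
    n_right: int
    n_fwd: int
    n_rev: int
    long_flag: bool
    R_inv: int
    R_ref: int = 0
    ir: Optional[IRPair] = None
    signal_read_ids: frozenset = frozenset()

    @property
    def length(self) -> int:
        return self.end - self.start


def _point_interval_distance(pos: int, start: int, end: int) -> int:
    if pos < start:
        return start - pos
    if pos > end:
        return pos - end
    return 0


def bin_signals_with_ir(
    signals: Sequence[InversionSignal],
    ir_db: Sequence[IRPair],
    cfg: ClusterConfig,
) -> Tuple[Dict[IRPair, SignalBin], List[InversionSignal]]:
    """Assign signals to IR bins; return (bins, leftover signals).

    A signal matches an IR pair when its estimated left breakpoint lies
    within X bp of the left repeat interval and its right breakpoint within
    X bp of the right repeat interval.  Each signal joins at most one bin
    (the first matching IR in sorted order); matched signals are removed
    from the stream before distance binning.
    """
    x = cfg.bin_distance_X
    trees: Dict[str, IntervalTree] = {}
    for idx, ir in enumerate(sorted(ir_db, key=lambda p: (p.chrom, p.left_start))):
        trees.setdefault(ir.chrom, IntervalTree()).addi(
            ir.left_start - x, ir.left_end + x + 1, (idx, ir)
        )
    bins: Dict[IRPair, SignalBin] = {}
    leftover: List[InversionSignal] = []
    for sig in signals:
        tree = trees.get(sig.chrom)
        best = None
        if tree is not None:
            for hit in tree[sig.ref_start]:
                idx, ir = hit.data
                if _point_interval_distance(sig.ref_start, ir.left_start, ir.left_end) > x:
                    continue
                if _point_interval_distance(sig.ref_end, ir.right_start, ir.right_end) > x:
                    continue
                if best is None or idx < best[0]:
                    best = (idx, ir)
        if best is None:
            leftover.append(sig)
        else:
            bins.setdefault(best[1], SignalBin(ir=best[1])).add(sig)
    return bins, leftover


def bin_signals_by_distance(
    signals: Sequence[InversionSignal], cfg: ClusterConfig
) -> List[SignalBin]:
    """Single-linkage distance binning against a running-mean representative.

    ``signals`` must be sorted by (chrom, ref_start).  A signal joins the
    first bin (in creation order) on the same chromosome whose running mean
    start and end are both less than X bp away; otherwise it opens a new bin.
    """
    x = cfg.bin_distance_X
    bins: List[SignalBin] = []
    open_bins: Dict[str, List[SignalBin]] = {}
    for sig in signals:
        placed = False
        for b in open_bins.get(sig.chrom, ()):
            if (
                abs(sig.ref_start - b.mean_start) < x
                and abs(sig.ref_end - b.mean_end) < x
            ):
                b.add(sig)
                placed = True
                break
        if not placed:
            b = SignalBin()
            b.add(sig)
            bins.append(b)
            open_bins.setdefault(sig.chrom, []).append(b)
    return bins


def validate_and_call(sbin: SignalBin, cfg: ClusterConfig) -> Optional[InversionCall]:
    """Turn a bin into an inversion call, or reject it.

    Requires at least one supporting read on each strand and at each
    breakpoint side, and total support R_inv >= min_support_reads, where a
    read contributes one count per side it supports.
    """
    sigs = sbin.signals
    if not sigs:
        return None
    chrom = sigs[0].chrom
    # one support unit per read per breakpoint signal class: a read crossing
    # both breakpoints contributes two units, duplicate signals of one read
    # at the same breakpoint contribute one
    units = {(s.read_id, s.side, s.strand) for s in sigs}
    n_left = sum(1 for _, side, _ in units if side == LEFT)
    n_right = sum(1 for _, side, _ in units if side == RIGHT)
    n_fwd = sum(1 for _, _, strand in units if strand == FORWARD)
    n_rev = sum(1 for _, _, strand in units if strand == REVERSE)
    r_inv = n_left + n_right
    if min(n_left, n_right, n_fwd, n_rev) < 1 or r_inv < cfg.min_support_reads:
        return None
    starts = [s.ref_start for s in sigs]
    ends = [s.ref_end for s in sigs]
    start = int(round(sum(starts) / len(starts)))
    end = int(round(sum(ends) / len(ends)))
    mech_nahr = any(s.mechanism == NAHR for s in sigs)
    return InversionCall(
        chrom=chrom,
        start=start,
        end=end,
        left_bp_start=min(starts),
        left_bp_end=max(starts),
        right_bp_start=min(ends),
        right_bp_end=max(ends),
        mechanism=NAHR if mech_nahr else "NHEJ",
        ir_overlap=max(s.ir_overlap for s in sigs),
        n_left=n_left,
        n_right=n_right,
        n_fwd=n_fwd,
        n_rev=n_rev,
        long_flag=(end - start) > cfg.long_inversion_L,
        R_inv=r_inv,
        ir=sbin.ir,
        signal_read_ids=frozenset(s.read_id for s in sigs),
    )


def cluster_signals(
    signals: Sequence[InversionSignal],
    ir_db: Optional[Sequence[IRPair]] = None,
    cfg: ClusterConfig | None = None,
) -> List[InversionCall]:
    """IR-pass then distance-pass binning, validation, sorted calls."""
    cfg = cfg or ClusterConfig()
    all_bins: List[SignalBin] = []
    leftover = list(signals)
    if ir_db:
        ir_bins, leftover = bin_signals_with_ir(signals, ir_db, cfg)
        all_bins.extend(ir_bins.values())
    all_bins.extend(bin_signals_by_distance(leftover, cfg))
    calls = [c for b in all_bins if (c := validate_and_call(b, cfg)) is not None]
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls
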