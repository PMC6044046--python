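"""Extraction of inversion signals from long-read sub-alignments.

A long read crossing an inversion breakpoint is reported by the aligner as
several sub-alignments (a primary record plus supplementary records and/or
``SA`` tag entries).  This module collects those sub-alignments per read,
filters them, and classifies adjacent opposite-orientation pairs into
breakpoint-level inversion signals, annotated with the mechanism (NAHR when
the two sub-alignments overlap on the read by more than the inverted-repeat
threshold, NHEJ otherwise).

Coordinates are 0-based half-open throughout.  Read-space coordinates are
always expressed on the original (sequenced) read orientation: for
reverse-strand alignments the clip lengths are mirrored, so that adjacency
of sub-alignments can be evaluated on the original molecule.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple, Union

import pysam

logger = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"
LEFT = "left"
RIGHT = "right"
NAHR = "NAHR"
NHEJ = "NHEJ"

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# CIGAR op consumption (query, reference)
_CONSUMES = {
    "M": (True, True),
    "I": (True, False),
    "D": (False, True),
    "N": (False, True),
    "S": (True, False),
    "H": (False, False),
    "P": (False, False),
    "=": (True, True),
    "X": (True, True),
}


@dataclass(frozen=True)
class SubAlignment:
    """One aligned segment of a read.

    ``read_start``/``read_end`` are on the original read orientation;
    ``ref_start``/``ref_end`` are 0-based half-open reference coordinates.
    """

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str  # FORWARD or REVERSE
    mapq: int

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start:
            raise ValueError(f"empty reference interval for {self.read_id}")
        if self.read_end <= self.read_start:
            raise ValueError(f"empty read interval for {self.read_id}")

    @property
    def read_length_aligned(self) -> int:
        return self.read_end - self.read_start


@dataclass(frozen=True)
class InversionSignal:
    """A sub-alignment pair supporting one inversion breakpoint.

    ``ref_start``/``ref_end`` are the estimated left and right inversion
    breakpoints implied by the pair: the junction-side endpoints of the two
    sub-alignments (reference ends when the first-in-read sub-alignment is
    forward, reference starts when it is reverse) pinpoint both breakpoints.
    """

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    side: str  # LEFT or RIGHT
    strand: str  # FORWARD or REVERSE
    mechanism: str  # NAHR or NHEJ
    ir_overlap: int  # bp of read-interval overlap between the pair


@dataclass
class ScanConfig:
    min_subalignment_len: int = 500
    nahr_overlap_min: int = 500
    min_mapq: int = 0

    def __post_init__(self) -> None:
        if min(self.min_subalignment_len, self.nahr_overlap_min, self.min_mapq) < 0:
            raise ValueError("ScanConfig fields must be nonnegative")


def _parse_cigar_string(cigar: str) -> List[Tuple[str, int]]:
    return [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]


def _cigar_lengths(ops: List[Tuple[str, int]]) -> Tuple[int, int, int, int]:
    """Return (leading clip, trailing clip, aligned query length, reference length)."""
    lead = trail = 0
    i = 0
    while i < len(ops) and ops[i][0] in "SH":
        lead += ops[i][1]
        i += 1
    j = len(ops)
    while j > i and ops[j - 1][0] in "SH":
        trail += ops[j - 1][1]
        j -= 1
    q = sum(n for op, n in ops[i:j] if _CONSUMES[op][0])
    r = sum(n for op, n in ops[i:j] if _CONSUMES[op][1])
    return lead, trail, q, r


def _normalise_cigar_key(cigar: str) -> str:
    # SA tags write soft clips where supplementary records may use hard clips
    return cigar.replace("H", "S")


def _read_coords(lead: int, trail: int, qlen: int, is_reverse: bool) -> Tuple[int, int]:
    """Original-read coordinates of the aligned interval, mirroring clips."""
    if is_reverse:
        return trail, trail + qlen
    return lead, lead + qlen


def _subaln_from_record(rec: pysam.AlignedSegment) -> Tuple[SubAlignment, str]:
    cigar = rec.cigarstring
    parsed = _parse_cigar_string(cigar)
    lead, trail, qlen, _rlen = _cigar_lengths(parsed)
    rs, re_ = _read_coords(lead, trail, qlen, rec.is_reverse)
    sub = SubAlignment(
        read_id=rec.query_name,
        chrom=rec.reference_name,
        ref_start=rec.reference_start,
        ref_end=rec.reference_end,
        read_start=rs,
        read_end=re_,
        strand=REVERSE if rec.is_reverse else FORWARD,
        mapq=rec.mapping_quality,
    )
    key = (sub.chrom, sub.ref_start, sub.strand, _normalise_cigar_key(cigar))
    return sub, key


def _subalns_from_sa_tag(rec: pysam.AlignedSegment) -> List[Tuple[SubAlignment, tuple]]:
    out = []
    try:
        sa = rec.get_tag("SA")
    except KeyError:
        return out
    for entry in sa.rstrip(";").split(";"):
        if not entry:
            continue
        fields = entry.split(",")
        if len(fields) != 6:
            logger.warning("malformed SA entry %r on read %s", entry, rec.query_name)
            continue
        chrom, pos, strand, cigar, mapq, _nm = fields
        parsed = _parse_cigar_string(cigar)
        lead, trail, qlen, rlen = _cigar_lengths(parsed)
        if qlen == 0 or rlen == 0:
            continue
        is_rev = strand == "-"
        rs, re_ = _read_coords(lead, trail, qlen, is_rev)
        ref_start = int(pos) - 1
        sub = SubAlignment(
            read_id=rec.query_name,
            chrom=chrom,
            ref_start=ref_start,
            ref_end=ref_start + rlen,
            read_start=rs,
            read_end=re_,
            strand=REVERSE if is_rev else FORWARD,
            mapq=int(mapq),
        )
        out.append((sub, (chrom, ref_start, sub.strand, _normalise_cigar_key(cigar))))
    return out


def collect_subalignments(
    bam: Union[str, pysam.AlignmentFile, Iterable[pysam.AlignedSegment]],
) -> Dict[str, List[SubAlignment]]:
    """Collect sub-alignments per read from a BAM/SAM stream.

    Sub-alignments are taken both from primary/supplementary records and from
    ``SA`` tags, deduplicated by (chrom, ref_start, strand, CIGAR).  Secondary
    and unmapped records are ignored; records without a CIGAR are skipped with
    a warning.  Only reads with at least two sub-alignments on the same
    chromosome are retained.
    """
    close = False
    if isinstance(bam, str):
        bam = pysam.AlignmentFile(bam, check_sq=False)
        close = True
    records = bam.fetch(until_eof=True) if isinstance(bam, pysam.AlignmentFile) else bam

    per_read: Dict[str, Dict[tuple, SubAlignment]] = {}
    try:
        for rec in records:
            if rec.is_unmapped or rec.is_secondary:
                continue
            if rec.cigarstring is None:
                logger.warning("read %s has no CIGAR; skipped", rec.query_name)
                continue
            bucket = per_read.setdefault(rec.query_name, {})
            sub, key = _subaln_from_record(rec)
            bucket.setdefault(key, sub)
            for sub2, key2 in _subalns_from_sa_tag(rec):
                bucket.setdefault(key2, sub2)
    finally:
        if close:
            bam.close()

    out: Dict[str, List[SubAlignment]] = {}
    for read_id, bucket in per_read.items():
        subs = list(bucket.values())
        counts: Dict[str, int] = {}
        for s in subs:
            counts[s.chrom] = counts.get(s.chrom, 0) + 1
        if max(counts.values(), default=0) >= 2:
            out[read_id] = subs
    return out


def filter_subalignments(alns: List[SubAlignment], cfg: ScanConfig) -> List[SubAlignment]:
    """Apply the length, MAPQ and read-interval containment filters.

    Sub-alignments shorter than ``cfg.min_subalignment_len`` on the read, or
    whose read interval is strictly contained in another's, are removed.
    Exactly equal read intervals keep the higher-MAPQ one (tie: first seen).
    Output is sorted by read_start (then read_end).
    """
    kept = [
        a
        for a in alns
        if a.read_length_aligned >= cfg.min_subalignment_len and a.mapq >= cfg.min_mapq
    ]
    survivors: List[SubAlignment] = []
    for i, a in enumerate(kept):
        drop = False
        for j, b in enumerate(kept):
            if i == j:
                continue
            if b.read_start <= a.read_start and a.read_end <= b.read_end:
                if (a.read_start, a.read_end) == (b.read_start, b.read_end):
                    # equal intervals: keep higher mapq, tie keeps earlier
                    if (b.mapq, -j) > (a.mapq, -i):
                        drop = True
                        break
                else:
                    drop = True
                    break
        if not drop:
            survivors.append(a)
    survivors.sort(key=lambda s: (s.read_start, s.read_end))
    return survivors


def _signal_from_pair(a: SubAlignment, b: SubAlignment, cfg: ScanConfig) -> InversionSignal:
    strand = a.strand
    side = LEFT if a.ref_start > b.ref_start else RIGHT
    low, high = (a, b) if a.ref_start <= b.ref_start else (b, a)
    if strand == FORWARD:
        bp_left, bp_right = low.ref_end, high.ref_end
    else:
        bp_left, bp_right = low.ref_start, high.ref_start
    if bp_left > bp_right:  # degenerate containment geometry; order defensively
        bp_left, bp_right = bp_right, bp_left
    overlap = max(0, a.read_end - b.read_start)
    mech = NAHR if overlap > cfg.nahr_overlap_min else NHEJ
    return InversionSignal(
        read_id=a.read_id,
        chrom=a.chrom,
        ref_start=bp_left,
        ref_end=bp_right,
        side=side,
        strand=strand,
        mechanism=mech,
        ir_overlap=overlap,
    )


def extract_signals(alns: List[SubAlignment], cfg: ScanConfig) -> List[InversionSignal]:
    """Classify read-adjacent opposite-orientation pairs as inversion signals.

    ``alns`` must be the filtered, read-sorted sub-alignments of one read.
    Every adjacent pair on the same chromosome and with opposite orientation
    yields one signal; same-orientation or cross-chromosome pairs yield none.
    """
    signals = []
    for a, b in zip(alns, alns[1:]):
        if a.chrom != b.chrom or a.strand == b.strand:
            continue
        signals.append(_signal_from_pair(a, b, cfg))
    return signals


def sort_signals(signals: Iterable[InversionSignal]) -> List[InversionSignal]:
    """Stable sort by (chrom, ref_start)."""
    return sorted(signals, key=lambda s: (s.chrom, s.ref_start))


def scan_bam(
    bam: Union[str, pysam.AlignmentFile],
    cfg: ScanConfig | None = None,
) -> List[InversionSignal]:
    """Full scan: collect, filter, pair and sort inversion signals."""
    cfg = cfg or ScanConfig()
    signals: List[InversionSignal] = []
    for read_id, alns in collect_subalignments(bam).items():
        filtered = filter_subalignments(alns, cfg)
        signals.extend(extract_signals(filtered, cfg))
    return sort_signals(signals)
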