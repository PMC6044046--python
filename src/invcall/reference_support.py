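"""Counting of reads supporting the non-inverted (reference) allele.

Reads that span an inversion breakpoint without a strand-switching split
support the reference allele, but high-error long reads can align across a
true inversion with pathological error patterns.  The filter compares the
alignment's substitution/insertion/deletion rates inside the inversion
region against a genome-wide per-alignment baseline: the alignment counts
only when all three rates are below the mean plus one standard deviation.

Rates are defined as event bases per aligned (match + mismatch) base, so an
insertion rate above 1 is possible for regions containing large insertions.
Substitutions are taken from extended CIGAR =/X operations when present,
otherwise from the NM tag (whole-alignment counts), the MD tag, or a
reference FASTA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
import pysam

from .clustering import InversionCall

logger = logging.getLogger(__name__)

# pysam cigar op codes
_M, _I, _D, _N, _S, _H, _P, _EQ, _X = range(9)
_REF_OPS = {_M, _D, _N, _EQ, _X}
_QUERY_OPS = {_M, _I, _S, _EQ, _X}
_ALIGNED_OPS = {_M, _EQ, _X}


@dataclass
class ErrorRateProfile:
    mean_sub: float
    mean_ins: float
    mean_del: float
    sd_sub: float
    sd_ins: float
    sd_del: float
    n_alignments_used: int

    def thresholds(self, k: float = 1.0, epsilon: float = 1e-9) -> Tuple[float, float, float]:
        """mean + k*SD per rate; with SD == 0 the threshold becomes
        mean + epsilon so that error-free alignments still pass a strict
        less-than comparison."""
        out = []
        for m, s in (
            (self.mean_sub, self.sd_sub),
            (self.mean_ins, self.sd_ins),
            (self.mean_del, self.sd_del),
        ):
            out.append(m + k * s if s > 0 else m + epsilon)
        return tuple(out)


class MissingErrorInfo(RuntimeError):
    """Raised when substitutions cannot be derived (no =/X, NM, MD or FASTA)."""


def _whole_alignment_counts(
    rec: pysam.AlignedSegment, fasta: Optional[pysam.FastaFile]
) -> Tuple[int, int, int, int]:
    """(sub, ins, del, aligned) base counts for the full alignment."""
    stats = rec.get_cigar_stats()[0]
    ins = stats[_I]
    dele = stats[_D]
    aligned = stats[_M] + stats[_EQ] + stats[_X]
    if stats[_EQ] or stats[_X]:
        return stats[_X], ins, dele, aligned
    if rec.has_tag("NM"):
        nm = rec.get_tag("NM")
        return max(0, nm - ins - dele), ins, dele, aligned
    sub = _count_mismatches_in_region(rec, None, fasta)
    return sub, ins, dele, aligned


def _count_mismatches_in_region(
    rec: pysam.AlignedSegment,
    region: Optional[Tuple[int, int]],
    fasta: Optional[pysam.FastaFile],
) -> int:
    """Mismatch count from MD tag or reference FASTA, optionally restricted
    to a reference window."""
    if rec.has_tag("MD"):
        pairs = rec.get_aligned_pairs(matches_only=True, with_seq=True)
        return sum(
            1
            for _q, r, s in pairs
            if s is not None
            and s.islower()
            and (region is None or region[0] <= r < region[1])
        )
    if fasta is not None:
        seq = rec.query_sequence
        if seq is None:
            raise MissingErrorInfo("alignment lacks SEQ; cannot compare to reference")
        ref = fasta.fetch(rec.reference_name, rec.reference_start, rec.reference_end).upper()
        n = 0
        for q, r in rec.get_aligned_pairs(matches_only=True):
            if region is not None and not (region[0] <= r < region[1]):
                continue
            if seq[q].upper() != ref[r - rec.reference_start]:
                n += 1
        return n
    raise MissingErrorInfo(
        "cannot derive substitutions: no =/X CIGAR, NM or MD tag, and no reference FASTA"
    )


def estimate_error_profile(
    bam: Union[str, pysam.AlignmentFile],
    reference_fasta: Optional[str] = None,
    max_alignments: int = 10_000,
) -> ErrorRateProfile:
    """Genome-wide error-rate baseline from the first min(10000, all)
    primary alignments in file order."""
    close = False
    if isinstance(bam, str):
        bam = pysam.AlignmentFile(bam, check_sq=False)
        close = True
    fasta = pysam.FastaFile(reference_fasta) if reference_fasta else None
    subs, inss, dels = [], [], []
    try:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.cigarstring is None:
                continue
            s, i, d, a = _whole_alignment_counts(rec, fasta)
            if a == 0:
                continue
            subs.append(s / a)
            inss.append(i / a)
            dels.append(d / a)
            if len(subs) >= max_alignments:
                break
    finally:
        if close:
            bam.close()
        if fasta is not None:
            fasta.close()
    if not subs:
        raise ValueError("no usable primary alignments in BAM")
    sub, ins, dele = (np.asarray(v, dtype=float) for v in (subs, inss, dels))
    ddof = 1 if len(subs) > 1 else 0
    return ErrorRateProfile(
        mean_sub=float(sub.mean()),
        mean_ins=float(ins.mean()),
        mean_del=float(dele.mean()),
        sd_sub=float(sub.std(ddof=ddof)),
        sd_ins=float(ins.std(ddof=ddof)),
        sd_del=float(dele.std(ddof=ddof)),
        n_alignments_used=len(subs),
    )


def region_error_rates(
    rec: pysam.AlignedSegment,
    call: InversionCall,
    fasta: Optional[pysam.FastaFile] = None,
) -> Optional[Tuple[float, float, float]]:
    """(sub, ins, del) rates of one alignment inside the call's inversion
    region (max(left bp start, aln start), min(right bp end, aln end)).

    Returns None when the clipped region is empty or contains no aligned
    bases.  Insertions are counted at their anchor position inside the
    region; the insertion rate may exceed 1.
    """
    lo = max(call.left_bp_start, rec.reference_start)
    hi = min(call.right_bp_end, rec.reference_end)
    if hi <= lo:
        return None
    aligned = sub = ins = dele = 0
    use_extended = any(op in (_EQ, _X) for op, _ in rec.cigartuples)
    pos = rec.reference_start
    for op, n in rec.cigartuples:
        if op in _REF_OPS:
            seg_lo, seg_hi = max(pos, lo), min(pos + n, hi)
            inside = max(0, seg_hi - seg_lo)
            if op in _ALIGNED_OPS:
                aligned += inside
                if op == _X:
                    sub += inside
            elif op == _D:
                dele += inside
            pos += n
        elif op == _I:
            if lo <= pos < hi:
                ins += n
    if aligned == 0:
        return None
    if not use_extended:
        sub = _count_mismatches_in_region(rec, (lo, hi), fasta)
    return sub / aligned, ins / aligned, dele / aligned


def count_reference_reads(
    call: InversionCall,
    bam: Union[str, pysam.AlignmentFile],
    profile: ErrorRateProfile,
    reference_fasta: Optional[str] = None,
    sd_multiplier: float = 1.0,
) -> int:
    """Count breakpoint-spanning, low-error primary alignments at a call.

    A primary alignment contributes one count per breakpoint interval it
    fully contains (left and/or right), provided it does not belong to a
    read with a strand-switching split at this call and all three region
    error rates are strictly below mean + sd_multiplier * SD.  Updates and
    returns ``call.R_ref``.
    """
    close = False
    if isinstance(bam, str):
        bam = pysam.AlignmentFile(bam)
        close = True
    fasta = pysam.FastaFile(reference_fasta) if reference_fasta else None
    thr = profile.thresholds(sd_multiplier)
    r_ref = 0
    try:
        for rec in bam.fetch(call.chrom, max(0, call.left_bp_start), call.right_bp_end):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_name in call.signal_read_ids:
                continue
            spans_left = (
                rec.reference_start <= call.left_bp_start
                and rec.reference_end >= call.left_bp_end
            )
            spans_right = (
                rec.reference_start <= call.right_bp_start
                and rec.reference_end >= call.right_bp_end
            )
            if not (spans_left or spans_right):
                continue
            rates = region_error_rates(rec, call, fasta)
            if rates is None:
                continue
            if all(r < t for r, t in zip(rates, thr)):
                r_ref += int(spans_left) + int(spans_right)
    finally:
        if close:
            bam.close()
        if fasta is not None:
            fasta.close()
    call.R_ref = r_ref
    return r_ref
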