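"""VCF 4.2 serialization of inversion calls.

Calls are written as symbolic ``<INV>`` records with SVTYPE/END, the
inferred mechanism (NAHR/NHEJ), the inverted-repeat overlap, and the
breakpoint uncertainty intervals.  The sample column carries GT, GQ
(integer Phred, capped at 99) and the supporting read counts DR (reference)
and DV (inversion); the full-precision genotype quality is kept in INFO/RQ.
Internal coordinates are 0-based half-open and converted to 1-based
inclusive at this boundary only.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from .clustering import InversionCall
from .genotyper import GenotypeResult

FILTER_LONG = "LongInversion"
FILTER_LOW = "LowSupport"

_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=MECH,Number=1,Type=String,Description="Inferred mechanism (NAHR or NHEJ)">',
    '##INFO=<ID=IROVL,Number=1,Type=Integer,Description="Maximum read-space overlap of the sub-alignment pair (bp); >0 indicates an inverted repeat">',
    '##INFO=<ID=BPLEFT,Number=2,Type=Integer,Description="1-based interval of left-breakpoint estimates">',
    '##INFO=<ID=BPRIGHT,Number=2,Type=Integer,Description="1-based interval of right-breakpoint estimates">',
    '##INFO=<ID=RQ,Number=1,Type=Float,Description="Full-precision Phred genotype quality">',
    '##FILTER=<ID=LongInversion,Description="Inversion longer than the long-inversion threshold">',
    '##FILTER=<ID=LowSupport,Description="Fewer supporting reads than required">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality (capped at 99)">',
    '##FORMAT=<ID=DR,Number=1,Type=Integer,Description="Reads supporting the reference allele">',
    '##FORMAT=<ID=DV,Number=1,Type=Integer,Description="Reads supporting the inverted allele">',
    '##ALT=<ID=INV,Description="Inversion">',
]


def build_header(contigs: Dict[str, int], sample: str = "SAMPLE") -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for line in _HEADER_LINES:
        header.add_line(line)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_sample(sample)
    return header


def write_vcf(
    calls: Sequence[Tuple[InversionCall, GenotypeResult]],
    contigs: Dict[str, int],
    path: str,
    sample: str = "SAMPLE",
    reference_fasta: Optional[str] = None,
    min_support_reads: int = 3,
) -> None:
    """Write calls (with genotypes) as a sorted VCF 4.2 file.

    The REF base at POS is taken from ``reference_fasta`` when supplied and
    is "N" otherwise.  A call extending beyond its contig raises ValueError.
    """
    header = build_header(contigs, sample)
    fasta = pysam.FastaFile(reference_fasta) if reference_fasta else None
    ordered = sorted(calls, key=lambda cg: (cg[0].chrom, cg[0].start))
    try:
        with pysam.VariantFile(path, "w", header=header) as vcf:
            for i, (call, gt) in enumerate(ordered):
                if call.chrom not in contigs:
                    raise ValueError(f"call on undeclared contig {call.chrom}")
                if call.end > contigs[call.chrom]:
                    raise ValueError(
                        f"call {call.chrom}:{call.start}-{call.end} exceeds contig length "
                        f"{contigs[call.chrom]}"
                    )
                ref_base = "N"
                if fasta is not None:
                    ref_base = fasta.fetch(call.chrom, call.start, call.start + 1).upper() or "N"
                rec = vcf.new_record(
                    contig=call.chrom,
                    start=call.start,
                    stop=call.end,
                    alleles=(ref_base, "<INV>"),
                    id=f"INV{i + 1}",
                )
                rec.info["SVTYPE"] = "INV"
                rec.info["MECH"] = call.mechanism
                rec.info["IROVL"] = call.ir_overlap
                rec.info["BPLEFT"] = (call.left_bp_start + 1, call.left_bp_end + 1)
                rec.info["BPRIGHT"] = (call.right_bp_start + 1, call.right_bp_end + 1)
                rec.info["RQ"] = float(gt.quality)
                if call.long_flag:
                    rec.filter.add(FILTER_LONG)
                elif call.R_inv < min_support_reads:
                    rec.filter.add(FILTER_LOW)
                else:
                    rec.filter.add("PASS")
                rec.samples[sample]["GT"] = gt.gt
                rec.samples[sample]["GQ"] = min(99, int(round(gt.quality)))
                rec.samples[sample]["DR"] = call.R_ref
                rec.samples[sample]["DV"] = call.R_inv
                vcf.write(rec)
    finally:
        if fasta is not None:
            fasta.close()


def read_calls_vcf(path: str) -> List[dict]:
    """Parse a VCF produced by :func:`write_vcf` (or a compatible caller)
    back into plain dictionaries with 0-based half-open coordinates."""
    out = []
    with pysam.VariantFile(path) as vcf:
        sample = list(vcf.header.samples)[0] if list(vcf.header.samples) else None
        for rec in vcf:
            if rec.info.get("SVTYPE") != "INV" and "<INV>" not in (rec.alts or ()):
                continue
            gt = None
            dr = dv = None
            if sample is not None:
                fmt = rec.samples[sample]
                alleles = fmt.get("GT")
                if alleles and None not in alleles:
                    dose = sum(alleles)
                    gt = {0: "refref", 1: "refinv", 2: "invinv"}.get(dose)
                dr = fmt.get("DR")
                dv = fmt.get("DV")
            out.append(
                {
                    "chrom": rec.chrom,
                    "start": rec.start,
                    "end": rec.stop,
                    "mechanism": rec.info.get("MECH"),
                    "filter": list(rec.filter.keys()),
                    "genotype": gt,
                    "R_ref": dr,
                    "R_inv": dv,
                    "quality": rec.info.get("RQ"),
                }
            )
    return out
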