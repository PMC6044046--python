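"""Readers and writers for the package's tab-delimited side formats.

The IR database is tab-delimited with one pair per line:
chrom, left_start, left_end, right_start, right_end[, identity]
(0-based half-open).  Truth tables use
chrom, start, end, mechanism, genotype.  BED output is 0-based half-open.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

from .clustering import IRPair
from .simulator import TruthRecord


class FormatError(ValueError):
    pass


def read_ir_db(path: str) -> List[IRPair]:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (5, 6):
                raise FormatError(f"{path}:{lineno}: expected 5 or 6 columns, got {len(fields)}")
            try:
                pairs.append(
                    IRPair(
                        chrom=fields[0],
                        left_start=int(fields[1]),
                        left_end=int(fields[2]),
                        right_start=int(fields[3]),
                        right_end=int(fields[4]),
                        identity=float(fields[5]) if len(fields) == 6 else 1.0,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return sorted(pairs, key=lambda p: (p.chrom, p.left_start))


def write_ir_db(pairs: Sequence[IRPair], path: str) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                f"{p.chrom}\t{p.left_start}\t{p.left_end}\t{p.right_start}\t{p.right_end}"
                f"\t{p.identity:.4f}\n"
            )


def write_truth_table(truth: Sequence[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tmechanism\tgenotype\n")
        for t in truth:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.mechanism}\t{t.genotype}\n")


def read_truth_table(path: str) -> List[dict]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            out.append(
                {
                    "chrom": fields[0],
                    "start": int(fields[1]),
                    "end": int(fields[2]),
                    "mechanism": fields[3],
                    "genotype": fields[4],
                }
            )
    return out


def write_bed(regions: Sequence[Tuple[str, int, int]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")
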