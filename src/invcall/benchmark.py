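"""Scoring of predicted inversions against a simulated truth set.

A prediction is a true positive when its interval and a truth interval
reciprocally overlap by at least the threshold (each interval covered by at
least that fraction of the other).  Matching is greedy by overlap and
one-to-one.  Positive predictive value, sensitivity and genotype
consistency are reported overall and per mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    n_truth: int
    n_predicted: int
    ppv: Optional[float]  # None (NA) when there are no predictions
    sensitivity: float
    gc: Optional[float]  # genotype consistency among TPs with genotypes
    matches: List[Tuple[int, int]] = field(default_factory=list)  # (pred idx, truth idx)
    by_mechanism: Dict[str, dict] = field(default_factory=dict)


def reciprocal_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    """min(overlap/len(a), overlap/len(b)) for two half-open intervals."""
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def _interval(obj) -> Tuple[str, int, int]:
    if isinstance(obj, dict):
        return obj["chrom"], obj["start"], obj["end"]
    return obj.chrom, obj.start, obj.end


def _genotype(obj) -> Optional[str]:
    if isinstance(obj, dict):
        return obj.get("genotype")
    return getattr(obj, "genotype", None)


def _mechanism(obj) -> Optional[str]:
    if isinstance(obj, dict):
        return obj.get("mechanism")
    return getattr(obj, "mechanism", None)


def benchmark(
    predicted: Sequence,
    truth: Sequence,
    threshold: float = 0.90,
) -> BenchmarkResult:
    """Score predictions against truth by reciprocal-overlap matching.

    ``predicted`` and ``truth`` items need chrom/start/end attributes or
    keys, optionally genotype ("refinv"/"invinv") and mechanism.
    """
    candidates = []
    for pi, p in enumerate(predicted):
        pc, ps, pe = _interval(p)
        for ti, t in enumerate(truth):
            tc, ts, te = _interval(t)
            if pc != tc:
                continue
            ro = reciprocal_overlap((ps, pe), (ts, te))
            if ro >= threshold:
                candidates.append((ro, pi, ti))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_p, used_t = set(), set()
    matches: List[Tuple[int, int]] = []
    for ro, pi, ti in candidates:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        matches.append((pi, ti))
    tp = len(matches)
    fp = len(predicted) - tp
    fn = len(truth) - tp
    ppv = tp / len(predicted) if predicted else None
    sens = tp / len(truth) if truth else 0.0

    def _gc(pairs: List[Tuple[int, int]]) -> Optional[float]:
        scored = [
            (pi, ti)
            for pi, ti in pairs
            if _genotype(predicted[pi]) is not None and _genotype(truth[ti]) is not None
        ]
        if not scored:
            return None
        ok = sum(1 for pi, ti in scored if _genotype(predicted[pi]) == _genotype(truth[ti]))
        return ok / len(scored)

    by_mech: Dict[str, dict] = {}
    for mech in sorted({m for t in truth if (m := _mechanism(t)) is not None}):
        t_idx = [i for i, t in enumerate(truth) if _mechanism(t) == mech]
        pairs = [(pi, ti) for pi, ti in matches if ti in set(t_idx)]
        by_mech[mech] = {
            "n_truth": len(t_idx),
            "tp": len(pairs),
            "sensitivity": len(pairs) / len(t_idx) if t_idx else 0.0,
            "gc": _gc(pairs),
        }

    return BenchmarkResult(
        tp=tp,
        fp=fp,
        fn=fn,
        n_truth=len(truth),
        n_predicted=len(predicted),
        ppv=ppv,
        sensitivity=sens,
        gc=_gc(matches),
        matches=matches,
        by_mechanism=by_mech,
    )
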