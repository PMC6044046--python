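"""Inverted-repeat length versus inversion-size analysis.

Across NAHR inversions there is a near-linear log-log relationship between
the length of the flanking inverted repeats and the distance between them
(the inversion size without the repeats).  This module fits that ordinary
least-squares regression of log10(distance) on log10(mean IR length),
filters candidate IR pairs by the two-sided OLS prediction interval at a
chosen level (default 90%), and merges surviving regions BEDTools-style
(book-ended intervals merge).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from .clustering import IRPair


@dataclass
class RegressionModel:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    residual_sd: float  # sqrt(SSE / (n - 2)), log10 units
    n: int
    x_mean: float
    sxx: float

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x

    def prediction_halfwidth(self, x: float, level: float = 0.90) -> float:
        """Half-width of the two-sided level prediction interval at x."""
        if not (0.0 < level <= 1.0):
            raise ValueError("level must be in (0, 1]")
        if level == 1.0:
            return math.inf
        tq = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        se = self.residual_sd * math.sqrt(1.0 + 1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx)
        return tq * se


def fit_loglog_regression(pairs: Sequence[Tuple[float, float]]) -> RegressionModel:
    """OLS of y = log10(distance) on x = log10(mean IR length).

    ``pairs`` holds (ir_length, distance) in bp, all positive; at least three
    points are required for the slope t-test and prediction intervals.
    """
    if len(pairs) < 3:
        raise ValueError("at least 3 (IR length, distance) pairs required")
    arr = np.asarray(pairs, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("IR lengths and distances must be positive")
    x = np.log10(arr[:, 0])
    y = np.log10(arr[:, 1])
    res = stats.linregress(x, y)
    n = len(x)
    resid = y - (res.intercept + res.slope * x)
    sse = float(np.sum(resid**2))
    return RegressionModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        residual_sd=math.sqrt(sse / (n - 2)),
        n=n,
        x_mean=float(x.mean()),
        sxx=float(np.sum((x - x.mean()) ** 2)),
    )


def prediction_interval_filter(
    ir_pairs: Sequence[IRPair],
    model: RegressionModel,
    level: float = 0.90,
) -> List[IRPair]:
    """Keep IR pairs whose log10(distance) lies inside the two-sided
    ``level`` prediction interval at their log10(mean IR length)."""
    out = []
    for p in ir_pairs:
        if p.gap <= 0 or p.mean_length <= 0:
            continue
        x = math.log10(p.mean_length)
        y = math.log10(p.gap)
        hw = model.prediction_halfwidth(x, level)
        if abs(y - model.predict(x)) <= hw:
            out.append(p)
    return out


def merge_regions(
    intervals: Sequence[Tuple[str, int, int]],
) -> List[Tuple[str, int, int]]:
    """Sort and union overlapping or book-ended intervals per chromosome."""
    for chrom, start, end in intervals:
        if end <= start:
            raise ValueError(f"malformed interval {chrom}:{start}-{end}")
    merged: List[Tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


def ir_candidate_regions(
    ir_pairs: Sequence[IRPair],
    model: RegressionModel,
    level: float = 0.90,
) -> List[Tuple[str, int, int]]:
    """Filter IR pairs by the prediction interval and merge the surviving
    outer spans (left repeat start to right repeat end) into candidate
    inversion regions."""
    survivors = prediction_interval_filter(ir_pairs, model, level)
    spans = [(p.chrom, p.left_start, p.right_end) for p in survivors]
    return merge_regions(spans)
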