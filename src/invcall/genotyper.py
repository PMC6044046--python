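"""Binomial genotype model for inversion calls.

Given counts of reads supporting the reference allele (``R_ref``) and the
inverted allele (``R_inv``), the genotype posterior is

    P(G | R_ref, R_inv)  ∝  P(R_ref, R_inv | G) P(G)

with per-read misassignment rates eps1 (inversion read counted as reference)
and eps2 (the converse):

    ref/ref : (1 - eps1)^R_ref * eps2^R_inv
    ref/inv : ((1-eps1)/2 + eps2/2)^R_ref * (eps1/2 + (1-eps2)/2)^R_inv
    inv/inv : eps1^R_ref * (1 - eps2)^R_inv

Priors follow Hardy-Weinberg equilibrium with a uniform allele prior
(0.25 / 0.5 / 0.25).  The genotype quality is the Phred-scaled ratio of the
second-best to the best posterior, Q = -10 log10(P_2nd / P_1st).

All likelihood arithmetic is done in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Tuple

from scipy.special import logsumexp

REFREF = "refref"
REFINV = "refinv"
INVINV = "invinv"
MISSING = "missing"

GENOTYPES: Tuple[str, str, str] = (REFREF, REFINV, INVINV)

#: VCF GT strings for each genotype label
GT_STRINGS = {REFREF: (0, 0), REFINV: (0, 1), INVINV: (1, 1), MISSING: (None, None)}


@dataclass
class GenotyperConfig:
    eps1: float = 0.01  # P(inversion-supporting read observed as reference-supporting)
    eps2: float = 0.01  # converse
    prior_refref: float = 0.25
    prior_refinv: float = 0.5
    prior_invinv: float = 0.25
    max_quality: float = 1000.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.eps1 < 1.0 and 0.0 <= self.eps2 < 1.0):
            raise ValueError("eps1/eps2 must lie in [0, 1)")
        total = self.prior_refref + self.prior_refinv + self.prior_invinv
        if abs(total - 1.0) > 1e-9:
            raise ValueError("genotype priors must sum to 1")

    @property
    def priors(self) -> Tuple[float, float, float]:
        return (self.prior_refref, self.prior_refinv, self.prior_invinv)


@dataclass
class GenotypeResult:
    genotype: str  # one of GENOTYPES, or MISSING when no reads observed
    posterior: Tuple[float, float, float]
    quality: float

    @property
    def gt(self) -> Tuple[int | None, int | None]:
        return GT_STRINGS[self.genotype]


def _xlogy(x: int, y: float) -> float:
    """x * log(y) with the empty-product convention 0 * log(0) = 0."""
    if x == 0:
        return 0.0
    if y == 0.0:
        return -math.inf
    return x * math.log(y)


def genotype_likelihood(r_ref: int, r_inv: int, genotype: str, cfg: GenotyperConfig | None = None) -> float:
    """Log-likelihood log P(R_ref, R_inv | G) for one genotype branch."""
    cfg = cfg or GenotyperConfig()
    if r_ref < 0 or r_inv < 0:
        raise ValueError("read counts must be nonnegative")
    e1, e2 = cfg.eps1, cfg.eps2
    if genotype == REFREF:
        return _xlogy(r_ref, 1.0 - e1) + _xlogy(r_inv, e2)
    if genotype == REFINV:
        return _xlogy(r_ref, (1.0 - e1) / 2.0 + e2 / 2.0) + _xlogy(
            r_inv, e1 / 2.0 + (1.0 - e2) / 2.0
        )
    if genotype == INVINV:
        return _xlogy(r_ref, e1) + _xlogy(r_inv, 1.0 - e2)
    raise ValueError(f"unknown genotype {genotype!r}")


def phred_quality(posterior: Sequence[float], max_quality: float = 1000.0) -> float:
    """Q = -10 log10(P_2nd / P_1st) for a normalized posterior vector."""
    total = float(sum(posterior))
    if abs(total - 1.0) > 1e-6:
        raise ValueError("posterior is not normalized")
    ranked = sorted(posterior, reverse=True)
    p1, p2 = ranked[0], ranked[1]
    if p2 <= 0.0 or p1 <= 0.0:
        return max_quality
    q = -10.0 * math.log10(p2 / p1)
    return min(max(q, 0.0), max_quality)


def genotype_call(r_ref: int, r_inv: int, cfg: GenotyperConfig | None = None) -> GenotypeResult:
    """Maximum-posterior genotype with Phred-scaled quality.

    With no observed reads at all the call is reported as missing with Q=0
    rather than as the prior argmax.  Ties are broken in the order
    refref < refinv < invinv and flagged by Q=0.
    """
    cfg = cfg or GenotyperConfig()
    log_post = [
        genotype_likelihood(r_ref, r_inv, g, cfg)
        + (math.log(p) if p > 0.0 else -math.inf)
        for g, p in zip(GENOTYPES, cfg.priors)
    ]
    norm = logsumexp(log_post)
    posterior = tuple(math.exp(lp - norm) for lp in log_post)
    if r_ref == 0 and r_inv == 0:
        return GenotypeResult(MISSING, posterior, 0.0)
    best = max(range(3), key=lambda i: (posterior[i], -i))
    q = phred_quality(posterior, cfg.max_quality)
    return GenotypeResult(GENOTYPES[best], posterior, q)
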