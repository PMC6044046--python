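# Methods

## Signal model

A long read crossing an inversion junction splits into two sub-alignments
of opposite orientation. Writing the inversion as the reference interval
[L, R) (0-based half-open), the four read classes — which junction is
crossed × sequencing orientation — produce four (strand, side) label
combinations, where *strand* is the orientation of the first sub-alignment
in read order and *side* records whether the first sub-alignment sits at a
higher reference position than the second. Two geometric facts drive the
implementation:

* every junction-crossing read determines **both** breakpoints: for pairs
  whose first sub-alignment is forward, the two sub-alignments' reference
  *end* coordinates equal (L, R); for first-reverse pairs, the reference
  *start* coordinates do. Signals therefore carry (left bp, right bp)
  estimates rather than the ragged outer extent of the pair, which makes
  the 2 kb clustering radius meaningful and the call coordinates (means of
  the per-signal estimates) unbiased.
* requiring a bin to contain both strand labels and both side labels
  demands reads from both junctions and both sequencing orientations —
  the guard against one-sided alignment artifacts.

For an NAHR inversion flanked by an inverted-repeat (IR) pair
[a1, b1) / [a2, b2) of length m, the aligner extends each sub-alignment
through the homologous half of the repeat, so left-junction signals
estimate (b1, b2) and right-junction signals (a1, a2), and the pair
overlaps on the read by ≈ m. The overlap is the NAHR classifier
(threshold: > 500 bp); averaging left- and right-junction estimates puts
the call at the IR midpoints.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_subalignment_len` | 500 bp | minimum sub-alignment length on the read |
| `nahr_overlap_min` | 500 bp | read-space pair overlap above which a signal is NAHR |
| `min_mapq` | 0 | optional MAPQ filter (off by default) |
| `bin_distance_X` | 2000 bp | clustering radius for IR and distance binning |
| `min_support_reads` | 3 | minimum R_inv for a call |
| `long_inversion_L` | 1 Mb | calls longer than this are flagged, not dropped |
| `eps1`, `eps2` | 0.01 | read misassignment rates in the genotype likelihood |
| priors | ¼, ½, ¼ | Hardy–Weinberg with a uniform allele prior |

Genotype quality is Q = −10·log₁₀(P₂ₙₔ/P₁ₛₜ), capped at 1000 when the
runner-up posterior underflows; the VCF sample column caps GQ at 99 and
keeps the full-precision value in INFO/RQ. With R_ref = R_inv = 0 the
genotype is reported missing (./.) rather than as the prior argmax.

## Reference-supporting reads

The error filter compares each candidate spanning alignment's
substitution/insertion/deletion rates *inside the inversion region*
(clipped to the alignment) against the genome-wide baseline: mean + 1 SD
of the per-alignment rates of the first min(10000, all) primary
alignments. Rates are events per aligned (match + mismatch) base, so the
insertion rate can exceed 1 in regions containing large insertions. When
all per-alignment rates are identical (error-free input) the SD is zero
and the threshold degenerates to mean + 1e-9 so perfect reads still pass
the strict comparison. Substitution counts come from extended (=/X)
CIGARs when present, otherwise from NM (whole alignment), MD, or a
reference FASTA; "spanning" means the primary alignment's reference
interval contains the breakpoint-uncertainty interval, and reads that
contributed inversion signals to the call are excluded.

## Simulator

The simulator emulates the benchmark design used for long-read inversion
callers: a uniform-random reference (default 5 Mb) carrying 10 NAHR loci
(IR pairs 500–3000 bp, second copy the reverse complement of the first,
inversion size 20–80 kb) and 10 NHEJ loci (5 at 1–4 kb, 5 log-uniform at
4–100 kb), genotypes Bernoulli(½) het/hom, reads of exponential length
(mean 3/6/9 kb, default 9 kb) from both strands at 5–40× (default 20×)
diploid coverage, and per-base substitution/insertion/deletion rates of
5.1/4.9/7.8%. The channel is calibrated so the *measured* rates (events
per aligned base) equal those settings: deletions hit haplotype positions
with probability p_del/(1+p_del); substitutions and single-base
insertions hit the surviving bases at the nominal rates.

Instead of an external aligner, the known read origin is converted
directly into sub-alignments: orientation flips inside inverted intervals,
NAHR junction pieces are extended through the homologous IR halves
(producing the read-space overlap the caller keys on), endpoints receive
0–20 bp of inward jitter, and records are emitted with exact =/X CIGARs,
SA tags, and one primary (longest piece) per read. Because planted IRs
are exact reverse complements, every `=` operation agrees with the
reference even inside extension zones (asserted in tests).

With identical repeats the NAHR inverted interval is only defined up to
the crossover position inside the repeat; the simulator flips and records
the canonical midpoint representative (IR midpoint to IR midpoint), which
is also the expected value of the caller's estimate. Truth intervals for
NHEJ are exact.

What the simulator deliberately does **not** model: alignment through
diverged or nested repeats, mapping ambiguity in non-unique sequence,
aligner-specific artifacts (indel-coding of short inversions, breakpoint
chopping), chimeric reads, coverage biases, and quality-score structure.
Passing benchmarks here therefore demonstrate the correctness of the
signal extraction, clustering, counting and genotyping machinery under
the stated error model — not robustness to real-aligner pathologies.

## Benchmarking

A prediction and a truth interval match when each covers ≥90% of the
other; matching is greedy by overlap and one-to-one. PPV = TP/(TP+FP),
sensitivity = TP/|truth|, genotype consistency = matching genotypes among
true positives (reported overall and per mechanism). With no predictions
PPV is reported as NA.

## IR-length / inversion-size analysis

Across NAHR inversions, log₁₀(distance between the repeats) is nearly
linear in log₁₀(mean IR length). The module fits this by ordinary least
squares (slope t-test, residual SD = √(SSE/(n−2))) and filters candidate
IR pairs by the standard two-sided OLS prediction interval (t(n−2)
quantile; default level 90%) on the distance at the observed IR length —
distance is the regression response, so the interval applies to it.
Surviving outer spans are merged BEDTools-style (book-ended intervals
merge). At level 1.0 the t-quantile diverges and every pair survives.

## Numerical choices

* Genotype likelihoods are computed in log space with the convention
  0·log 0 = 0 and normalized by logsumexp; posterior ties break in the
  order ref/ref < ref/inv < inv/inv and are flagged by Q = 0.
* Support counting uses unique (read, side, strand) units, so a read
  spanning both breakpoints contributes two units while duplicate signals
  of one read at one junction contribute one; R_inv = n_left + n_right by
  construction.
* Distance binning joins a signal to the first existing bin (creation
  order) whose running-mean start and end are both within X; on sorted
  input this is deterministic.
* Equal read intervals in the containment filter keep the higher-MAPQ
  sub-alignment (tie: first encountered); strictly contained intervals
  are always dropped.
* All internal coordinates are 0-based half-open; conversion to 1-based
  happens only in the VCF writer.

## Problem sizes

Default test and acceptance runs use a 5 Mb reference at 20× (≈11,000
reads), which completes in about a minute; unit tests use 0.3–1.5 Mb
genomes. The simulator accepts chromosome-scale configurations through
the same `SimConfig`.

## Known limitations

* NHEJ inversions shorter than ~1 kb approach the 500 bp sub-alignment
  floor and the breakpoint-jitter scale; the paper-style size classes
  start at 1 kb and so does the simulator.
* IR pairs wider than the 2 kb clustering radius are only merged across
  junctions when an IR database is supplied (the distance pass would
  split them); this mirrors the intended use with a reference-derived IR
  annotation.
* ε₁/ε₂ are fixed constants; estimating them from data is out of scope.
* Single-sample VCF only; no breakend (BND) representation.
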