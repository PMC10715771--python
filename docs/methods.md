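# Methods

## Problem setting

`copeaks` calls consensus open-chromatin peaks jointly from K ≥ 1 ATAC-seq
samples. Each chromosome is modeled as n consecutive fixed-width loci of
L bp (default L = 50); the inputs are per-sample, per-chromosome coverage
or enrichment tracks on that grid (bedGraph or fixedStep wiggle with
step = span = L), treated as given, opaque nonnegative values — read
preprocessing, normalization, and fragment-model smoothing are upstream
concerns. All coordinates are 0-based half-open; a chromosome length not
divisible by L loses its trailing partial locus (logged), so every locus
has identical width.

## Scoring

Each locus i is summarized across samples by three robust statistics:

- **g1, enrichment** — the cross-sample median (even K: midpoint of the
  two central order statistics). Medians make the score insensitive to a
  minority of outlier samples.
- **g2, dispersion** — the median absolute deviation about g1, unscaled
  (no 1.4826 consistency factor): the raw median of |s_ik − g1(i)|.
  For K = 1 it is identically 0.
- **g3, boundary volatility** — the largest absolute difference between
  g1(i) and its immediate neighbors, normalized by g1(i) + 1. One-sided at
  the chromosome ends; 0 by convention for a single-locus grid (logged).
  On a flat-top enriched block over flat background, g3 is maximal at the
  loci flanking the block edges and zero at block centers and deep
  background, so it sharpens peak boundaries.

The score is the thresholded linear combination
`S(i) = c1·g1 − c2·g2 + c3·g3` if `g1(i) ≥ τ` (inclusive comparison), else
0. Defaults c1 = c2 = c3 = 1, τ = 0. With defaults S(i) ≥ 0 always (for
nonnegative data at least half the samples lie within g1 of g1, so
g2 ≤ g1). Nondefault weights may produce negative scores; these loci are
*not* clamped and remain selectable, since the fragmentation term below
can still favor them. g3 is computed from raw g1, before any τ
thresholding.

## Selection as an optimization problem

The decision vector ℓ ∈ {0,1}ⁿ minimizes

    f(ℓ) = Σᵢ −S(i)·ℓᵢ + γ Σᵢ |ℓᵢ − ℓᵢ₊₁|

subject to the per-chromosome budget Σ ℓᵢ ≤ ⌊n·b⌋. The budget b ∈ [0,1]
(default 0.035) upper-bounds the selected fraction, reflecting estimates
that roughly 3–4% of the human genome is accessible; because
accessibility varies between chromosomes, b, γ, and τ can be overridden
per chromosome. The total-variation penalty weight γ ≥ 0 (default 1.0)
charges each selected-region boundary 2γ, so at fixed budget larger γ
produces fewer, longer peaks and can merge nearby enriched regions.

Exact integer solving is impractical at n ~ 10⁶, so the box relaxation
ℓᵢ ∈ [0,1] is solved instead. Introducing auxiliary variables
zᵢ ≥ |ℓᵢ − ℓᵢ₊₁| (two linear inequalities each; upper bound 1 is imposed,
safe since |ℓᵢ − ℓᵢ₊₁| ≤ 1 and provably inactive at optimum for γ > 0)
turns the relaxation into an LP over 2n−1 variables with 1 + 2(n−1)
sparse constraint rows. At any optimum with γ > 0 the auxiliaries are
tight, so the LP value OPT equals the relaxed objective at the truncated
solution; for γ = 0 the auxiliaries are cost-free and are reset to
|ℓᵢ − ℓᵢ₊₁| post hoc for consistent reporting. OPT lower-bounds f over
every feasible binary vector.

**Near-integrality is not assumed.** LP optima here are often but not
always nearly binary; flat score plateaus in particular produce genuinely
fractional optimal faces (see "Fixture design" below), and every
downstream stage accepts arbitrary fractional input.

## Solver

The LP is built as a `scipy.sparse` CSR matrix and solved with scipy's
`linprog` HiGHS backend. The default method is `highs-ipm` (interior
point with crossover): the fragmentation LP is massively degenerate at
genomic n — long runs of tied scores — where simplex variants stall
(minutes at n = 10⁵) while IPM converges in seconds, and crossover still
lands on a vertex, keeping the auxiliary variables numerically tight
(relative objective-consistency error at machine precision in testing).
Any other `linprog` method string can be injected; no commercial solver
is required or supported. Solver failure (impossible for a well-posed
instance — ℓ = 0 is always feasible) raises with the backend's
diagnostics. Decision values within `integrality_eps` (default 1e-9) of
0/1 are snapped, then clipped to [0,1].

The LP sees only the length-n score vector, so solve cost is independent
of K; scoring is the only K-dependent stage (O(nK)). This is asserted
empirically by timing solves of identical score vectors derived from
K = 2 and K = 200 cohorts.

## Randomized rounding

Given ℓᴸᴾ, one rounding iteration draws independent Bernoulli(ℓᵢᴸᴾ)
decisions. The candidate set is N such draws (default N = 50) plus the
floor-rounded solution (values within `integrality_eps` of 1 snapped up
first), which is feasible by construction; infeasible draws are
discarded, not repaired. The best feasible candidate by objective wins;
ties break toward fewer selected loci, then the earliest-generated
candidate (floor first, then draws in order), making the outcome
deterministic under a seed. Each chromosome uses an RNG stream seeded by
(run seed, CRC-32 of the chromosome name), so per-chromosome results are
independent of processing order.

Holding the auxiliary coordinates at their LP values, the randomized
objective is unbiased for OPT by linearity of expectation. (Re-evaluating
the true total variation of a draw instead gives E ≥ OPT, since
E|X − Y| ≥ |EX − EY|; the unbiasedness statement and its test use the
fixed-auxiliary form.) A Markov/Hoeffding argument bounds the probability
that N iterations contain a solution with at most nb(1+a) selections and
near-optimal objective from below by `1 − (1/c + e^{−2n(ab)²})^N`,
evaluable via `rounding_success_bound(n, b, a, c, N)` for a > 0, c > 1; if the
hypothesis `1/c + e^{−2n(ab)²} < 1` fails the bound is vacuous and 0 is
returned with a warning. Because OPT ≤ 0 under default scoring, the
multiplicative near-optimality event is interpreted as
`f − OPT ≤ (c−1)·|OPT|`; the literal reading `f ≤ c·OPT` would be
unsatisfiable for c > 1.

## Output

Maximal runs of selected loci merge into half-open peaks
`[origin + (i_first−1)L, origin + i_last·L)`, written as sorted BED6 with
LF endings: name `<chrom>_<start>_<end>`, score = run-mean S rescaled so
the maximum score in the vector maps to 1000 (clamped to [0,1000]),
strand "." (the assay is unstranded). Total peak bp always equals
L · (number of selected loci), and the peak count equals the number of
0→1 transitions in the zero-padded decision vector.

## Synthetic data

`generate_synthetic_signals` emulates a multi-sample enrichment profile:
background loci draw |N(0, noise)| (half-normal, so background has a
nonzero median floor as real coverage does); planted non-overlapping
blocks add `amplitude + N(0, dispersion·amplitude)` per sample, clipped
at 0. Defaults noise = 0.5 and dispersion = 0.1 model a modest background
relative to block amplitudes of ~5 and a ~10% between-sample coefficient
of variation — a well-behaved replicate cohort. The generator does **not**
emulate read-level count noise, GC or mappability bias, copy-number
variation, sample-specific signal-to-noise differences, or ragged peak
shapes; passing tests therefore demonstrate correctness of the
optimization machinery and pipeline contracts on idealized signals, not
calling performance on real ATAC-seq.

### Fixture design

Two consequences of the score's edge-reward were discovered while
designing the recovery fixtures and are properties of the model, not
bugs:

- A background locus flanking a block of amplitude A has g1 = 0 and
  g3 = A, hence S = A — as high as the block interior. With a generous
  budget the optimizer legitimately selects one flanking locus per edge,
  so recovered peaks extend ~1 locus beyond sharp planted blocks.
- With τ = 0, a flat-top block admits a fractional LP optimum that
  spreads mass uniformly over block + flanks (the TV penalty shrinks
  under spreading faster than the reward is diluted), and rounding then
  returns a random near-budget subset.

The zero-noise *exact*-recovery check therefore uses τ = 1 (a
conservative enrichment threshold, which zeroes the zero-median flanks
and makes the planted window the unique integral optimum) with the
budget set to the planted fraction; the noisy recovery check runs at
full defaults and measures Jaccard overlap with truth (~0.94 at n = 10⁴,
K = 20, amplitude 5, 3.3% planted, budget 3.5%).

## Problem sizes used in checks

Optimality and equivalence checks run on 200 random instances with
n ∈ [4,12], K ∈ [1,10] against an exhaustive 2ⁿ oracle (hard cap n = 20);
recovery and concentration checks at n = 10⁴, K ∈ {5, 20}; determinism
and solve-cost checks at n up to 10⁵ with 3 interleaved timing repeats.
These sizes exercise every code path, including genuinely fractional LP
optima, while keeping the full suite to a couple of minutes.

## Known limitations

- Scores, budget and penalty are per-chromosome; no cross-chromosome
  coupling or global budget exists.
- No summit estimation or per-peak significance: the model produces
  intervals and relative scores only.
- The budget is a hard cap supplied by the user; no data-driven budget
  tuning is implemented.
- bigWig tracks are not read directly; convert to bedGraph/wiggle
  upstream.
- The brute-force oracle is test-only and refuses n > 20.
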