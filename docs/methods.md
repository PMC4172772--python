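# Methods

## The data model

The analysis operates on three objects:

- an **incidence matrix**: 23 titanosaur species × 14 Late Cretaceous
  stratigraphic formations, cell = 1 when the species is recorded in the
  formation. Row totals are range sizes (formations per species), column
  totals are formation richness. The packaged matrix has 33 occurrences and
  column totals (4, 7, 1, 5, 1, 2, 3, 3, 1, 1, 2, 1, 1, 1).
- an **abundance vector**: fossil records per species, the input to Chao1.
- a **body-size table**: estimated total length in meters per species.
  Missing lengths are stored as NaN and excluded (with a warning), never
  imputed silently.

Cell parsing accepts only literal `0`/`1` after whitespace stripping;
anything else is an error naming the row and column, because silent
coercion would mask transcription mistakes. All-zero rows or columns load
with a warning and are dropped by default before co-occurrence analysis
(configurable): a species with no records can never participate in a swap
and only deflates the mean pairwise score.

### Known discrepancies in the source data

Two documented inconsistencies are preserved rather than resolved:

1. The source text calls the Allen Formation the second-richest with six
   species, but its printed matrix column sums to five. The package follows
   the printed matrix.
2. The source reports an observed C-score of 1.96 against a null mean of
   1.91. Applying the printed CU formula to the printed matrix gives
   exactly 377/253 ≈ 1.4901 (verified here by independent brute-force pair
   enumeration), not 1.96. Either the analyzed matrix differed from the
   printed one or a non-standard averaging was used. The package implements
   the printed formula on the printed matrix and does not target 1.96.
   The qualitative conclusion — observed inside the central null mass —
   is unaffected and is what the acceptance checks assert.

### Missing supplementary values

Per-species fossil counts and the full body-length table exist only in a
supplementary file that is not part of the packaged data. Consequences:

- The packaged size table carries only the two lengths printed in the main
  text (*Rocasaurus muniozi* 8 m, *Puertasaurus reuili* 30 m); the other 21
  species are flagged missing.
- So that the size-overlap stage of the full pipeline can still be
  exercised end to end, `synthetic_titanosaur_sizes()` provides a clearly
  labelled **synthetic stand-in**: the two published extremes kept verbatim,
  every missing species drawn log-uniformly between them from a fixed
  internal seed (20140923). It carries no information about the real
  species and is flagged in the report provenance; conclusions drawn from
  that stage characterize the method, not titanosaur biology.
- The published Chao1 of 57 (CI 36–115) cannot be recomputed without the
  per-fossil counts; the estimator is instead verified on its closed-form
  cases and on synthetic assemblages with known richness.

## Chao1 richness

`chao1 = sobs + f1²/(2 f2)`, falling back to the bias-corrected term
`f1(f1−1)/(2(f2+1))` when `f2 = 0` (flagged in the result, since the
classic ratio is undefined there). The confidence interval is the Chao
(1987) log-normal interval: with `T = chao1 − sobs`, `G = f1/f2`,
`var = f2(G²/2 + G³ + G⁴/4)` (a separate closed form when `f2 = 0`), and
`K = exp(z √ln(1 + var/T²))`, the bounds are `sobs + T/K` and
`sobs + T·K`; `T = 0` collapses to a point interval at `sobs`. Estimates
are never rounded internally; the published "57" is treated as rounded.

Accumulation curves pool **individual fossil records** (not formations) in
random order, recomputing `S_obs` and Chao1 at each level and averaging
over randomizations (default 1,000). The source is self-contradictory on
whether records are drawn with or without replacement; both modes are
implemented and *without* replacement is the default.

## C-score under the fixed-fixed null

The observed statistic is the mean of `CU = (r_i − S)(r_j − S)` over all
`R(R−1)/2` unordered pairs, every pair included regardless of its CU. The
implementation computes shared-site counts via a matrix product; the test
suite checks it against a deliberately naive double-loop oracle on 200
random matrices.

The null holds both margins fixed and samples matrices with the
sequential-swap chain: pick two distinct rows and two distinct columns
uniformly; if the 2×2 submatrix is a checkerboard, flip it. Defaults:

- `burn_in = 30,000` attempted swaps (the 23×14 fixture has 33 ones, so
  this is far past mixing for matrices of this scale);
- `thin = 1` successful swap between recorded matrices, mirroring the
  sequential behavior of the classic co-occurrence software, where
  consecutive null matrices differ by one swap;
- `iterations = 10,000` recorded matrices, the study's setting.

Tail probabilities use the add-one correction
`p_upper = (1 + #{null ≥ obs})/(1 + iterations)`, counting the observed
matrix as a null realization; ties count toward the tail (conservative).
Both tails and the SES are always reported. A matrix with no swappable
submatrix (e.g. perfectly nested) yields a degenerate result: point-mass
null, zero spread, SES reported as NaN.

Calibration: assemblages drawn from the fixed-fixed null itself (long swap
chains from the fixture) are rejected at the nominal α = 0.05 rate within
a 99% binomial envelope over 200 replicates; a perfectly segregated
checkerboard construction is rejected at p ≤ 0.01. Both checks run in the
acceptance suite at reduced chain lengths (300 recorded matrices per
inner test, 3,000-attempt burn-in; 500 swaps between replicate
assemblages), sizes chosen to keep the calibration experiment's total
Markov-chain work proportionate to the rest of the suite.

## Size overlap

Lengths are log10-transformed by default, sorted ascending, and
differenced into `n−1` segments. Metrics: the variance of segments
(population convention, divide by the segment count; `ddof` configurable
and recorded) and the minimum segment. Both are order- and
relabeling-invariant, and multiplying all raw sizes by a constant leaves
log-scale segments unchanged.

The source mandates a log transform yet describes minimum segment length
"in meters"; the package computes both metrics on the transformed scale by
default and exposes `transform="identity"` for the literal meters reading.

The default null retains the observed minimum and maximum and draws the
`n−2` interior values i.i.d. uniform between them (the classic fixed-
endpoint arrangement for spacing tests); `fix_endpoints=False` randomizes
all `n`. A source-pool mode draws `n`-species subsets from a larger
candidate pool with colonization weights. The source's literal settings —
the assemblage itself as its own pool with unit weights — are degenerate
(every pseudocommunity would equal the observed assemblage), so the
uniform-interior null is taken as the operative method; pool mode demands
a strictly larger pool and raises otherwise.

Direction of the structure calls: variance → lower tail (structured
assemblages space species *evenly*), minimum segment → upper tail
(structured assemblages keep the closest pair *far apart*). Tied sizes are
legal, give a zero minimum segment, and warn.

For `n = 3` with fixed endpoints the null minimum segment has the closed
form `E[min(U, span−U)] = span/4`, used as an exact oracle in the tests.

## Synthetic data

Generators provide ground-truth inputs for every stage, all deterministic
under a seed:

- `make_checkerboard`: maximal segregation; species pairs split across two
  disjoint site blocks, within-pair CU = (block size)².
- `make_nested`: perfect nesting, every CU = 0 — the degenerate chain case.
- `make_random_margins`: margin-preserving shuffles of any template.
- `make_abundances`: exact singleton/doubleton targets; remaining counts
  follow a shifted geometric with mean ≈ 5 — only (F1, F2) enter Chao1, so
  the tail shape is cosmetic.
- `make_sizes`: `even_log` (geometric spacing, zero segment variance),
  `uniform` (log-uniform), `clustered` (two Gaussian clumps, s.d. 2% of the
  log-range, which makes spacing power tests sharp at n = 15).

What the generators deliberately do not emulate: taphonomic and
preservational biases, spatially autocorrelated sampling effort, or any
relationship between abundance, body size and preservation. Passing tests
therefore demonstrate statistical correctness and calibration of the
methods, not that real fossil assemblages satisfy the nulls' assumptions.

## Pipeline and reproducibility

`run_paper_analysis` fans a single top-level seed out to per-stage
sub-seeds via `SeedSequence`, hashes every input file, and echoes all
parameters into the report, so a report's provenance block reproduces it
bit-for-bit. Defaults mirror the study: 10,000 randomizations for each
null model, log10 transform, 95% confidence level, 1,000 accumulation
randomizations. The richness stage is skipped with a notice when no
abundance file is given; the size stage falls back to the synthetic
stand-in (flagged) when fewer than three real lengths are known. Plots
(accumulation curve, null histograms) are optional artifacts; the JSON
report is canonical.

## Limitations

- With 33 occurrences in a 23×14 matrix the fixed-fixed null space is
  small; consecutive swap samples are autocorrelated (thin = 1), which the
  add-one p-value tolerates but which inflates Monte Carlo error relative
  to independent sampling.
- The size-overlap analysis of the packaged assemblage is a method
  demonstration only, given the stand-in sizes.
- Only Chao1 (not Chao2/ACE/jackknife), only the C-score (not CHECKER,
  V-ratio or COMBO), and only the fixed-fixed sequential-swap null are
  implemented — the scope of the original analysis.
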