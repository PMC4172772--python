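# paleonull

Null-model statistics for paleoecological assemblages: nonparametric
species-richness estimation, co-occurrence analysis, and body-size overlap
analysis, with the Late Cretaceous (Campanian–Maastrichtian) South American
titanosaur assemblage packaged as the worked dataset.

The question these tools address: when a set of extinct species is recorded
across a handful of stratigraphic formations, is there any sign that
deterministic processes — interspecific competition, habitat filtering, size
partitioning — structured who coexisted with whom? Or are the observed
patterns indistinguishable from chance once sampling structure is held
fixed? The package is aimed at quantitative paleoecologists and community
ecologists who want these classic tests scriptable, seeded, and testable.

## Statistics implemented

**Chao1 richness.** From per-species record counts, with `S_obs` observed
species, `F1` singletons and `F2` doubletons:

    S_chao1 = S_obs + F1² / (2 F2)

(bias-corrected term `F1(F1−1)/(2(F2+1))` when `F2 = 0`), with the Chao
(1987) log-normal 95% confidence interval and randomized accumulation
curves over individual fossil records.

**C-score co-occurrence.** For each species pair occupying `r_i` and `r_j`
formations with `S` shared, the checkerboard units are
`CU = (r_i − S)(r_j − S)`; the C-score is the mean CU over all pairs.
Significance comes from the fixed-fixed null: matrices with identical row
and column totals sampled by the sequential-swap Markov chain (random 2×2
checkerboard submatrix flips), with standardized effect size and add-one
tail probabilities `p = (1 + #{null ≥ obs}) / (1 + iterations)`.

**Size overlap.** Species body lengths are log10-transformed, sorted, and
differenced into *segments*. The variance of segments (structure = observed
significantly smaller, i.e. unusually even spacing) and the minimum segment
(structure = observed significantly larger) are tested against
pseudocommunities whose interior sizes are drawn uniformly between the
observed extremes, or against draws from a larger source pool.

## Worked example

```python
from paleonull import run_paper_analysis, is_structured

report = run_paper_analysis(seed=1)   # packaged fixture, 10,000 randomizations
```

which prints, via `examples/full_reproduction.py`:

```
co-occurrence (C-score, fixed-fixed sequential swap)
  observed 1.4901  null mean 1.5270  SES -0.789  P(null >= obs) 0.7763
size overlap (log10 segment lengths, synthetic stand-in sizes)
  variance:    observed 0.000691  P(null <= obs) 0.6986  structured: False
  min segment: observed 0.002326  P(null >= obs) 0.1450  structured: False
```

Reading: the 23 titanosaur species across 14 formations form 215 of 253
possible checkerboard pairs, but their mean checkerboard score (1.4901)
sits well inside the null distribution generated by 10,000 margin-preserving
swaps — no evidence of competitive segregation. Both size-overlap tests
likewise leave the observed spacing inside the central null mass. The
assemblage shows no detectable deterministic structure.

Two data caveats, detailed in `docs/methods.md`: only the two extreme body
lengths (8 m and 30 m) are published in the source's main text, so the
size-overlap stage runs on a clearly flagged synthetic stand-in table; and
per-fossil abundance counts are likewise unavailable, so the richness stage
is skipped unless you supply a `species,count` file.

Each script in `examples/` is a short narrative demo of one capability
(richness, co-occurrence, size overlap, full pipeline). A thin CLI mirrors
the library: `paleonull run --seed 1`, plus `richness`, `cooccur`,
`sizeoverlap` and `synth` subcommands.

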