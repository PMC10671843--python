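# Methods

## Coordinate model

All intervals are 0-based half-open (BED convention); touching intervals do
not overlap. A breakpoint supplied as a BED interval is reduced to the single
coordinate `floor((start + end) / 2)`; breakpoints are treated as single
positions, never as paired structural-variant junction ends. Chromosome order
is input order, and every sort respects it.

Genome sequence is normalized on read to the alphabet {A, C, G, T, N}: input
is uppercased, `U` becomes `T`, and any other character — including IUPAC
ambiguity codes such as `R` — is masked to `N`. The mask is deliberately
conservative: a degenerate genome position never counts as a motif match, and
randomized regions are never placed across masked positions. The per-
chromosome gap mask always equals the set of maximal `N` runs.

## Motif expansion and scanning

A degenerate motif over the IUPAC alphabet expands to the Cartesian product
of its per-position base sets; with per-position sets iterated in A<C<G<T
order the expansion is globally lexicographic, and each variant's index in
that order is its stable `variant_id`. The default recognition motif
`CCNCCNTNNCCNC` has five `N` positions and therefore 4⁵ = 1024 variants.

Scanning is exhaustive plain string matching: every occurrence of a concrete
variant is reported, overlapping occurrences included, on the forward strand
by default (`strand_mode="both"` adds reverse-complement occurrences on
forward coordinates, deduplicated per position). Forward-only is the default
because single-strand pattern matching is the standard exhaustive-scan
convention this pipeline reproduces; the flag exposes the alternative without
changing any other step. `scan_all_variants` runs one regex pass of the
degenerate pattern (overlapping matches via a lookahead capture) and buckets
each matched substring to its variant — provably identical to per-variant
scanning because variant hit sets are disjoint as sequences. Hit intervals
are never merged: the count-once statistic over windows makes merging
immaterial for the test, but per-variant hit counts would change, so the raw
occurrences are kept.

## Windows

A window of total width `w` (even, default 100 and 500 nt) around breakpoint
`p` is `[p − w/2, p + w/2)` — "width" is the whole flanking frame, not the
per-side margin (the per-side reading is one parameter change away). Windows
at chromosome edges are clipped rather than dropped, so the number of tested
regions always equals the number of breakpoints; windows are never merged
even when breakpoints are closer than `w`.

## Permutation test

The observed statistic is count-once overlap: the number of windows with at
least 1 bp intersection with any motif hit. The null re-places the *window*
set — windows are the smaller, length-homogeneous set, and randomizing the
query set is the standard convention for this family of region-overlap tests
— while motif hits stay fixed; `randomize="hits"` swaps the roles. Each
region is re-placed independently and uniformly over all valid starts
genome-wide: a chromosome is implicitly drawn with probability proportional
to `length − region_length + 1` minus mask-excluded starts, so every valid
placement of the genome is equally likely. Placements may overlap each other
and may change chromosome.

Statistics, for `n_perm` permutations (default 1000):

- `p = (1 + #{perm ≥ obs}) / (n_perm + 1)` for the "greater" alternative
  (mirrored for "less"); the +1 smoothing bounds p below by
  `1/(n_perm + 1)`, i.e. 1/1001 ≈ 0.001 at the default.
- `z = (obs − mean(perm)) / sd(perm)` with the sample sd (ddof = 1). A
  zero-spread null (e.g. an empty hit set) leaves z undefined (NaN, with a
  warning) rather than ±∞; the p-value remains valid.
- `alternative="auto"` (default) resolves to "greater" when
  `obs ≥ mean(perm)`, else "less".

The implementation is vectorized: all `n_perm × n_windows` placements of each
unique window length are drawn in one batch and tested against the merged,
sorted hit intervals with binary search, so a default-geometry test runs in
milliseconds and the whole 1024-variant screen stays a desk-scale
computation.

### Discreteness and calibration

With realistic geometry the null overlap count is a small integer (about
Poisson(0.4) under the default synthetic conditions: 60 windows of width 100
against 300 13-bp sites on 5 Mb). Permutation p-values on such a heavily
tied, discrete statistic are *conservative*: the attainable p-values cluster
on a few values, and the rejection rate at α = 0.05 measures ≈ 0.02 rather
than 0.05. The test suite asserts the direction of that deviation — the test
is never anti-conservative — and the exact-null enumeration test verifies
that the permutation distribution itself is correct to total variation
< 0.05. Calibration close to the nominal level is only expected when the
null statistic is large enough to be effectively continuous.

## Local (displacement) z-score

For offsets `d ∈ {−max_shift, …, 0, …, +max_shift}` (defaults:
`max_shift = 5 × width`, `step = width/2`) every window is shifted by `d`,
clipped at chromosome bounds, and the recomputed observed count is expressed
as a z-score using the *parent* test's null mean and sd — the null is not
re-simulated, so the profile is deterministic given the parent and the value
at `d = 0` equals the parent z exactly. A peak at 0 that collapses within one
window width demonstrates position-specific association.

## Screen, significance rule and consensus

`screen_all` runs one test per (variant × breakpoint set × width) with a
per-combination seed derived by stable hashing of
`(base_seed, variant_id, label, width)` — any single combination re-run in
isolation reproduces its row bit-for-bit. The significance flag is the raw
rule `p < 0.05 and |z| > 3`, applied per row with no multiple-testing
correction; Benjamini–Hochberg q-values are computed within each
(label × width) stratum and reported as an additional column, never used for
the flag. Because pooling over cancer types is a genuinely open choice, the
table exposes both summaries: variants significant in ≥ 1 combination and in
all combinations. Rows are sorted by (p, |z| descending) with deterministic
tie-breaks; failed combinations become rows with an error status instead of
vanishing. TSV serialization uses fixed float formatting so identical runs
are byte-identical.

The consensus of a set of equal-length variants is the per-position base
count matrix plus the minimal IUPAC code covering the bases with non-zero
count; by construction the consensus of *all* expansions of a degenerate
pattern is the pattern itself.

## Synthetic data generator

`SyntheticConfig` defaults define the study conditions used throughout the
tests: 2 chromosomes × 2.5 Mb (5 Mb total), GC 0.5, 300 planted occurrences
of the variant `CCACCATCACCAC` (a concrete expansion of the default motif),
60 breakpoints, proximity distance d = 50 bp. Background bases are i.i.d.
with `P(G) = P(C) = gc/2`; planted sites are uniform, non-overlapping
(rejection sampling, hard error after 10⁵ attempts). Each breakpoint is,
independently with probability `f`, placed uniformly within ±d of a uniformly
chosen planted site, else uniformly on the genome; truth labels
(enriched/background) are recorded. One global seed drives independent
derived substreams per artifact, so genomes, sites and each labeled
breakpoint set are individually reproducible.

Chance background occurrences of the motif are *not* scrubbed — a real
genome has them and the test must stay powerful despite them; tests that
need ground truth condition on the planted sites. Since the permutation test
is purely a region-geometry computation, the calibration and monotonicity
simulations use `plant_sites` (positions only) without materializing
sequence; `generate_genome` writes the identical positions into sequence
under the same seed, and the power test runs the full sequence + scan path.

The default multi-label fixture (`StudyProfile`) emulates the shape of a
four-cancer-type breakpoint catalog: labels BRC/LUAD/OV/HN with 150/170/230/
170 breakpoints (720 total, echoing the relative sizes of such catalogs) on
3 × 2 Mb, with enrichment fraction 0.5 per label as a realistic mid-strength
effect. What the generator does **not** emulate: sequence composition
heterogeneity (isochores, repeats), structural-variant mechanisms, paired
junction ends, chromatin or replication-timing covariates, and assembly gaps
at real-genome scale. Passing tests therefore demonstrate correctness of the
inference machinery under its stated null, not robustness to genome
compositional confounding — on real data, covariate-matched randomization
would be the appropriate extension.

## Problem sizes and numerical choices

Test and acceptance runs use the desk-scale geometry above: n_perm = 200 for
replicate simulations (400 null replicates, 50 replicates × 5 enrichment
fractions), n_perm = 1000 where the p-floor matters, n_perm = 20,000 for the
exact-null comparison on a 12-bp toy instance (3 windows of length 2, exact
distribution enumerated over all 11³ placements). These sizes were chosen so
every statistical contract is exercised with comfortable margins at
interactive runtimes. Degenerate inputs are handled explicitly: empty hit
sets give p = 1 and undefined z; empty window sets are a hard error; windows
clipped to < 1 bp by extreme shifts are excluded from the shifted count.

## Known limitations

- Genome-scale z-scores from real hg19-sized inputs are far larger than
  anything the desk-scale suite produces; the suite verifies properties
  (calibration direction, power, positional specificity, determinism), not
  genome-scale magnitudes.
- The uniform-placement null ignores sequence composition; motif density
  varies with GC content, so on real genomes the test can be confounded by
  regional composition (see generator caveats above).
- `annotate_nearest_feature` measures distance to feature starts on the same
  chromosome only; it is a distance annotation, not a gene-regulatory-domain
  assignment.
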