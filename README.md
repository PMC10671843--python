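# prdm9scan

Association analysis between PRDM9 recognition-motif occurrences and
structural-variant breakpoints in cancer genomes.

PRDM9 is the zinc-finger histone methyltransferase that positions meiotic
recombination hotspots by binding a degenerate 13-bp DNA motif,
`CCNCCNTNNCCNC`. Its aberrant activity in somatic cells has been linked to
genomic instability, raising the question whether concrete variants of that
motif sit near the double-strand-break (DSB) junctions mapped in tumor
genomes more often than chance placement would allow. `prdm9scan` answers
that question end to end:

1. **Expansion** — the degenerate motif's five `N` positions expand to
   4⁵ = 1024 concrete variants (any IUPAC pattern is supported).
2. **Scanning** — every variant is located exhaustively in a genome FASTA;
   overlapping occurrences are kept, masked (`N`) positions never match.
3. **Windows** — each breakpoint becomes a fixed-width flanking frame
   (100 nt and 500 nt by default) with the break at its center.
4. **Permutation test** — the observed count-once overlap statistic
   (number of windows containing ≥ 1 motif hit, `Ev_obs`) is compared with
   the null obtained by re-placing the windows uniformly on the genome
   `n_perm` times (`Ev_exp` = null mean). This yields

   - empirical p-value `p = (1 + #{perm ≥ obs}) / (n_perm + 1)`,
   - z-score `z = (obs − mean) / sd` of the permutation null,
   - a **local z profile**: z recomputed after shifting all windows by
     ±d bp against the unshifted null — a sharp peak at d = 0 shows the
     association is position-specific, not a broad regional effect.
5. **Screen** — the test runs for every (variant × breakpoint set × window
   width); a row is significant when `p < 0.05` and `|z| > 3`; significant
   variants are summarized into a position-count matrix and IUPAC consensus.

A synthetic-data module generates multi-chromosome genomes with planted
motif occurrences and breakpoint sets in which a controlled fraction `f` of
breakpoints falls within `d` bp of a planted site, so the whole pipeline and
its statistical guarantees are testable without any genome download.

## Worked example

Simulate a small study (one genome, two breakpoint sets — one enriched near
planted motif sites, one background) and screen the 4 variants of `CCNC`:

```sh
prdm9scan simulate --seed 2 --n-chroms 1 --chrom-length 200000 \
    --n-sites 50 --labels A=30:0.8,B=25:0.0 -o fixture
prdm9scan screen --genome fixture/genome.fa \
    --breakpoints A=fixture/breakpoints_A.bed,B=fixture/breakpoints_B.bed \
    --motif CCNC --widths 100 --n-perm 1000 --seed 7 -o out
```

which prints

```
8 rows -> out/screen.tsv; significant rows: 1; variants significant in >=1: 1
```

`out/screen.tsv` holds one row per (variant, label, width) with the observed
overlap, null mean/sd, z, p, BH q-value and significance flag. The planted
variant `CCAC` in label `A` reaches the p-value floor `1/1001 ≈ 0.001` with a
large positive z, while the same variant in the background set `B` and the
other three variants everywhere stay at chance level — exactly the separation
the screen exists to make. `out/localz/` holds the displacement profile of
each top hit; its z collapses to ≈ 0 once windows are shifted by more than a
window width.

The same operations are available as a library:

```python
from prdm9scan import (DegenerateMotif, expand_degenerate, SyntheticConfig,
                       generate_genome, generate_breakpoints, scan_motif,
                       make_windows, perm_test)

cfg = SyntheticConfig(seed=7, enrichment_fraction=0.8)   # 5-Mb genome
assembly, truth = generate_genome(cfg)
hits = scan_motif(assembly, cfg.planted_variant)
breaks = generate_breakpoints(cfg, truth, label="demo")
result = perm_test(make_windows(breaks, 100, assembly), hits, assembly,
                   n_perm=1000, seed=7)
print(result.observed, round(result.p_value, 4), round(result.z_score, 2))
# 51 0.001 80.44
```

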