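# mutspot

Statistical tooling for asking whether a cell phenotype is written in
the genome. Given a parental cell population and a derived population
enriched for the phenotype (e.g. monolayer breast-cancer cells versus
serially passaged tumorspheres enriched for stem-like cells), plus deep
targeted sequencing of single cells from each group, `mutspot`
implements the full inference chain:

1. **VAF-increase selection.** If a phenotype-carrying subpopulation
   expands between the parental and derived samples, SNVs private to it
   should rise in variant allele frequency (VAF). Each site's ref/alt
   read counts in the two samples form a 2×2 table tested with a
   two-sided Fisher exact test; sites with *P* < 0.1 **and** a strict
   VAF increase are selected.
2. **Hotspot calling.** Under a Poisson model of SNV placement, the
   distance *x* between adjacent selected sites is exponential with
   *P(x)* = 1 − e^(−λx), λ = 1/x̄. Distances with *P* < 0.01 are
   unusually short; maximal runs of ≥ *m* significant distances with at
   most *n* tolerated gaps (defaults *m* = 5, *n* = 1), shorter than
   100 kb, are hotspots. Each hotspot is scored with the hypergeometric
   upper tail of drawing its *m* significant distances in *n* + *m*
   draws from the genome-wide pool of *a* distances containing *b*
   significant ones.
3. **Single-cell concordance.** For a panel of single cells (3 test +
   2 reference by default) with per-position A/C/G/T read counts:
   base-weight vectors (count fractions) give pairwise Pearson
   correlations and Euclidean genetic distances; a position error rate
   PER = ΣBC/ΣTC estimated from the reference cells, inflated to
   p₀ = PER + c·√(PER/TC) with c = 1.64 (the 95% Gaussian quantile), is
   the null of an exact binomial upper-tail test (PBC) on the test
   group's mean background count; positions with PBC below a
   Bonferroni threshold (0.001/#positions) are candidate group-specific
   variants. All C(5,2) = 10 reference-pair relabelings are evaluated
   and the case-permutation ratio CPR = NP_case/(NP_perm + NP_case)
   calibrates the result: CPR ≈ 0.5 across thresholds means the
   "signal" is technical noise.

Because raw sequencing for such experiments is rarely shareable, the
package ships a first-class synthetic-data module that generates all
three modalities (Poisson SNV positions with planted clusters, paired
binomial read counts with planted VAF shifts, deep single-cell count
matrices with position-specific error rates and planted variants)
together with ground truth for scoring recovery.

## Worked example

```python
import numpy as np
from mutspot import (simulate_snv_positions, simulate_paired_counts,
                     select_increased_sites, fit_distance_model, call_hotspots,
                     simulate_base_count_matrix, concordance_analysis)

# two dense clusters planted on a 10 Mb chromosome (background 1e-5 SNV/bp)
genome = {"chr1": 10_000_000}
specs = [("chr1", 2_000_001, 2_001_000, 1000.0),
         ("chr1", 7_500_001, 7_501_000, 1000.0)]
positions, truth = simulate_snv_positions(genome, 1e-5, specs, seed=7)
model = fit_distance_model(positions)
for h in call_hotspots(model):
    print(f"hotspot {h.chrom}:{h.start}-{h.end}  length={h.length} bp  "
          f"m={h.m} n={h.n}  P={h.p_value:.3g}")
```

```
hotspot chr1:2000008-2000968  length=960 bp  m=10 n=0  P=8.65e-09
hotspot chr1:7500039-7500984  length=945 bp  m=13 n=0  P=1.18e-11
```

Both planted clusters are recovered, each with a hypergeometric *P*
many orders below the weakest-admissible-hotspot value of 1.988 × 10⁻⁴
(the tail at *a* = 30,774, *b* = 4003, *n* = 1, *m* = 5). VAF selection
on paired counts simulated at these positions (base VAF 0.1, a random
20% of sites shifted to 0.5 in the derived sample, mean depth 100):

```python
table, t2 = simulate_paired_counts(positions, base_vaf=0.1,
                                   shifted_fraction=0.2, shifted_vaf=0.5, seed=7)
sel = select_increased_sites(table, "2D", "SP4", alpha=0.1)
```

selects 33 of 129 sites, recovering all 27 true shifts (the remaining
selections are the expected false positives of a two-sided test at
α = 0.1 with a direction filter). Finally, a pure-noise single-cell
panel (10,000 positions, mean depth 4000×, mean error 0.005):

```python
matrix, _ = simulate_base_count_matrix(10_000, depth_law=(4000, 20),
                                       error_law=(0.005, 2000), seed=7)
res = concordance_analysis(matrix, ["R1", "R2"], ["T1", "T2", "T3"])
```

reports a minimum pairwise base-weight correlation of 1.0000 (to 4
decimals), inter- vs intra-group *t*-test *p* = 0.259, mean genetic
distance 0.00202, zero positions flagged at *P* < 1 × 10⁻⁷, and a mean
CPR of 0.66 for this replicate (single-replicate CPR means are ratios
of small counts and noisy; averaged over five seeds the null mean CPR
is 0.48) — the signature of two genomically identical groups.

## Command line

Thin wrappers over the same functions:

```
mutspot simulate --out-dir out --seed 1
mutspot select   --variants out/variants.tsv --out-dir out
mutspot hotspots --variants out/selected_sites.tsv --out-dir out
mutspot concord  --counts out/base_counts.tsv --out-dir out -r R1 -r R2
```

Each subcommand takes `--config config.yaml` with flag overrides and
logs the resolved configuration and seed.

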