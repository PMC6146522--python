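# Methods

## Overview

`mutspot` chains three statistical procedures: selection of SNV sites
whose variant allele frequency (VAF) increases from a parental to a
derived population, clustering of the selected sites into mutation
hotspots under an exponential inter-site-distance model, and a
single-cell concordance analysis that asks whether two groups of
single cells differ genetically at deep-sequenced panel positions.
A synthetic-data module generates all inputs with known ground truth.

## VAF-increase selection

At each site the ref/alt read counts of the two bulk samples form a
2×2 contingency table. The test is the two-sided Fisher exact test
(scipy's implementation, which sums the probabilities of all tables
with the observed margins at most as likely as the observed one); a
site is selected when *P* < α (default 0.1) **and** VAF_parental <
VAF_derived, both strict. Using a non-directional test plus a
direction filter means the null selection rate is at most α/2, and in
practice below it because the exact test is conservative at finite
depth (measured ≈ 0.04 at depth 100, α = 0.1).

Site filters applied first: exclusion of masked regions (segmental
duplication/repeat tracks supplied as BED) and of whole chromosomes
(mitochondrial, Y, unplaced contigs), and a read-depth window of
[10, 200]. Depth is ref + alt computed **per sample**; a site is
removed if any sample is out of range. The per-sample reading is the
stricter of the two possible conventions and is the documented choice.
Sites where a sample has zero depth have undefined VAF; they are
reported unevaluable, never selected, and logged.

## Hotspot calling

If SNV sites arrive as a homogeneous Poisson process, the distance *x*
between adjacent sites (computed within chromosomes only; with *s*
sites on *c* occupied chromosomes there are *s* − *c* distances) is
exponential, and

P(x) = 1 − e^(−λx),  λ = 1/x̄,

with x̄ the mean adjacent distance pooled genome-wide (a single fit,
not per chromosome — clustering is judged against the global site
density). A distance is significant when P(x) < 0.01, equivalently
x < −x̄·ln(0.99) ≈ 0.01·x̄.

The boolean significance sequence is segmented by run-length encoding
into maximal blocks that begin and end with significant distances,
contain at least *m* = 5 significant distances and at most *n* = 1
non-significant gaps (thresholds, configurable: the published minimum
requirement is read as m ≥ 5 and n ≤ 1). Blocks are grown greedily
left to right; a candidate start inside a block's leading run can only
produce a subset of the same block, so emitted blocks are maximal and
non-overlapping (asserted against an exhaustive window-scan oracle in
the tests). A trailing or leading gap is never absorbed — it would add
span without evidence. Hotspot length is last member position minus
first member position (a span; the +1 convention is not used), and
blocks longer than 100 kb are discarded.

Each surviving hotspot with composition (m, n) is scored with the
hypergeometric upper tail

P(X ≥ m),  X ~ Hypergeom(a, b, n + m),

where *a* is the genome-wide number of adjacent distances and *b* the
number of significant ones. The tail is computed in log space from
log-gamma binomial coefficients, summing the upper tail directly
(accurate for very small p; matches an exact-rational oracle to
~1e-13 over the full grid a ≤ 100). At the published pool
(a = 30,774, b = 4003) the weakest admissible hotspot (m = 5, n = 1)
scores 1.988 × 10⁻⁴.

## Single-cell concordance

Inputs are per-position A/C/G/T read counts for five single cells:
three test cells (the phenotype-positive group) and two reference
cells, at panel positions covered in every cell (positions missing
from any cell are dropped at read time). For each position and cell:
TC = total count, MC = major (modal) count, BC = TC − MC.

* **Base weights** are the count fractions (W_A, W_C, W_G, W_T);
  pairwise Pearson correlation over the concatenated per-position
  weight vectors and Euclidean **genetic distance**
  d = √Σ(W₁ₙ − W₂ₙ)² summarize overall similarity. (The distance is
  the "Pythagorean" per-component form; summing the weight differences
  before squaring would be identically zero since weights sum to 1.)
  Inter-group versus intra-group correlations are compared with a
  two-tailed two-sample t-test.
* **Position error rate.** From the reference pair,
  PER = ΣBC/ΣTC pooled per position. The binomial null probability is
  inflated by c standard errors: p₀ = PER + c·√(PER/TC_ref) with
  c = 1.64 (95% Gaussian quantile). TC_ref is the mean reference TC at
  the position (the scale of one cell's coverage; a config switch uses
  the summed TC instead). When PER = 0, p₀ is floored at
  1/(ΣTC_ref + 1) inside the test so that finite data can never declare
  a background read strictly impossible; the floor is logged when it
  binds.
* **PBC test.** For the test triple, successes = round(ΣBC/3) and
  trials = round(ΣTC/3) (rounding half away from zero — exact binomial
  tests need integers; averaging preserves the per-cell scale), and
  PBC = P(X ≥ successes | trials, p₀), the exact binomial upper tail.
  Positions with PBC below the family threshold 0.001/#positions are
  flagged.
* **Permutation and CPR.** All C(5,2) = 10 reference-pair splits are
  evaluated identically; the split matching the true grouping is the
  case, the other 9 are permutations. For thresholds t on a default
  grid of 101 points over [0, 0.1], NP(t) counts positions with
  PBC < t per scheme, and CPR = NP_case/(NP_perm + NP_case) per
  permutation. 0/0 is reported as undefined, not 0.5. A flat CPR near
  0.5 indicates the case grouping flags no more positions than random
  relabelings, i.e. no group-specific genetic signal.

## Synthetic data

* `simulate_snv_positions`: homogeneous Poisson background (default
  study scale 10⁷ bp at 10⁻⁵ SNV/bp ⇒ ~100 sites) with planted
  intervals at a multiplied rate; positions integer, deduplicated.
  Inter-site distances pass an exponential KS test at α = 0.01 in
  ≥ 95% of seeded runs.
* `simulate_paired_counts`: per site and sample, depth from a
  gamma-Poisson (negative-binomial-like) law with floor 1 — defaults
  (100, 10) for bulk WGS scale — and alternate count
  Binomial(depth, VAF). A configurable fraction of sites carries a
  shifted VAF in the derived sample (defaults 0.1 → 0.5).
* `simulate_base_count_matrix`: single-cell panel defaults 3 + 2 cells,
  depth law (4000, 20) matching deep amplicon coverage, per-position
  error rates drawn once from a Beta with mean 0.005 and concentration
  2000 and shared across cells (error is position-specific, not
  cell-specific); background reads split uniformly over non-major
  bases. Planted variants add a second allele at a given fraction in
  chosen cells; an optional dropout knob zeroes one allele of a planted
  heterozygous site to mimic whole-genome-amplification allele dropout
  (off by default — no published generative model exists for it).

All generators take one seed; identical seeds give byte-identical
output. Truth objects record planted clusters, shifted sites, planted
variants and the per-position error vector, sufficient to score every
downstream stage.

What the simulations do **not** model: amplification bias beyond the
optional dropout knob, mapping artifacts, strand effects, correlated
errors between neighboring positions, indels, and real genomic
heterogeneity of mutation rate. Passing tests therefore demonstrate
statistical correctness of the procedures under their own model
assumptions, not robustness to every artifact of real single-cell
sequencing.

## Numerical choices and degenerate inputs

* Hypergeometric and binomial tails are exact summations (log-gamma /
  scipy's survival functions), never normal approximations.
* Fisher two-sided p uses the conventional relative tie tolerance
  (1 + 1e-7) when comparing table probabilities.
* Fewer than two sites on every chromosome ⇒ empty distance model,
  no hotspots, logged. All-zero distances (duplicate positions) are
  rejected upstream by the table invariant.
* Zero-variance inputs to the correlation or t-test return NaN /
  p = 1 (identical constant groups) rather than raising mid-pipeline.
* Internal coordinates are 1-based inclusive everywhere; BED
  conversion happens only at I/O.

## Problem sizes

Default analysis and test scales — a 10⁷ bp genome at 10⁻⁵ SNV/bp for
hotspot recovery, 10⁴ panel positions at 4000× for concordance runs,
5-seed replication for calibration claims, and exhaustive oracle grids
capped at a ≤ 100 (hypergeometric), margins ≤ 60 (Fisher) and length
≤ 12 plus sampled length-50 sequences (block caller) — were chosen so
the full statistical behavior is exercised at desk scale. Planted
clusters in recovery tests use ~10³-fold rate enrichment, the density
regime real hotspots occupy (internal distances of tens of bp against
a genome-wide mean of ~10⁵ bp): detection under the exponential model
requires intra-cluster distances below ~1% of the pooled mean
distance, so enrichments of order 10–20× are undetectable by
construction, not by implementation choice.

## Known limitations

* The concordance machinery assumes every panel position is covered in
  every cell; it drops positions rather than imputing.
* CPR is a ratio of small counts at stringent thresholds; single-seed
  mean CPR is noisy and calibration statements should average seeds.
* When a true group-specific variant is present at high fraction,
  permutation schemes that move one carrier into the reference pair
  still detect the remaining carriers (the inflated p₀ does not fully
  absorb a 0.5-fraction allele), so CPR saturates near 1 only against
  relabelings whose reference pair contains no carriers; against mixed
  relabelings it sits near 0.5. CPR is a noise calibration, not a
  power statistic.
* The Fisher selection loop is per-site (exact tests are not
  vectorized); ~10⁴ sites take a few seconds.
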