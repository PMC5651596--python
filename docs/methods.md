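# Methods

## Model and conventions

All coordinates are 0-based half-open; 1-based file formats (genetic-map
text) are converted at the I/O boundary. A genetic map is a monotone mapping
`G: bp → cM`; between markers `G` is linearly interpolated and outside the
marker range it clamps to the terminal values, so an interval with no map
coverage has rate exactly 0 and is flagged. The average rate of `[s, e)` is
`(G(e) − G(s)) / ((e − s)/1e6)` cM/Mb; masked variants (e.g. excluding gene
bodies padded by 2 kb for intergenic analyses) divide the summed genetic
distance of the unmasked sub-segments by the unmasked length.

A link's *span* is the closed hull of its two anchors and its *distance* is
measured between anchor midpoints — a symmetric convention adopted because
the reference point within an anchor is not otherwise determined. Distance
classes are `[1 kb, 10 kb)`, `[10 kb, 100 kb)` and `[100 kb, 1 Mb]`;
distances outside are excluded from the stratified tests.

Rate-vs-distance curves report, per distance bin, the mean rate and a
half-width of `sd × 1.96 / 10`, with the sample standard deviation (ddof=1,
defined as 0 for singleton bins) and the fixed divisor 10 implemented
verbatim as the curve convention of this analysis style.

## Significance procedures

**Paired rank test.** Per-link rates are paired with their matched control's
rate and tested with a two-sided Wilcoxon signed-rank test. Zero differences
are dropped (classical convention, not Pratt), ties receive midranks. For
n ≤ 25 effective pairs the null distribution of the rank sum is computed
exactly by dynamic programming over doubled midranks (doubling makes
midranks integral); the two-sided p sums the two symmetric tails at the
smaller of W⁺/W⁻. Above n = 25 the tie-corrected normal approximation with
continuity correction is used. The commonly cited "two-way paired
Mann–Whitney U" has no standard paired form; the Wilcoxon signed-rank test
is the paired rank test this package implements, and the choice is recorded
in the results metadata.

**Median permutation test.** The null universe is the set of all
same-chromosome point pairs (e.g. array SNPs × TSSs) whose distance falls in
the class under test. The universe is never materialized: per left point the
feasible right-point range is located by binary search and flat sample
indices map back by arithmetic, so sampling is exactly uniform (verified
against full enumeration by chi-square). Per class, 10,000 medians of
equally sized draws form the null; the one-sided depletion p is
`(1 + #{null ≤ observed}) / (1 + n_perm)`, so the minimum attainable p at
10,000 permutations is `1/10001 < 1e-4`, exactly reaching the significance
threshold when the observed median ranks below every null median. A class is
flagged significant when every computed p-value for it is ≤ α (default
1e-4).

**Group comparison.** Depletion per group is mean(control) − mean(observed)
over per-link matched controls; the difference between two link groups is
tested by permuting group labels over the pooled per-link depletion values
(two-sided, +1-corrected).

## Matched controls

Four strategies, all preserving the link's chromosome and exact span length
except where noted:

* *length*: uniform random start;
* *rejection*: repeat length-matched draws until the Euclidean distance
  between normalized feature vectors (GC fraction, CpG density, SNP density,
  PRDM9 motif density) is < 0.01, up to 10,000 iterations; on exhaustion the
  best candidate is returned flagged unmatched and excluded from the paired
  test by default (the exhaustion path is a deliberate design choice of this
  package);
* *k-d tree*: candidates are enumerated on a 1-kb grid at 1 kb–1 Mb lengths
  (1-kb steps), indexed by normalized features including chromosome index
  and length themselves; the k = 1000 nearest neighbours are filtered —
  disjoint candidates nearer than 1 kb to the span, candidates overlapping
  it by more than 50% of the shorter interval, and (optionally)
  CTCF-containing candidates — and one survivor is drawn uniformly. Because
  chromosome and length are soft matching features here, k-d controls may
  differ in both. Genome-scale enumeration is supported only behind a
  subsampling stride with a candidate-count guard.
* *domain*: uniform same-length interval inside the (smallest) domain
  containing the span; uncontained links are skipped.

Feature normalization is min–max to [0, 1] per feature. The 0.01 tolerance
is applied in this normalized space: a raw-unit tolerance would be
dimensionally meaningless across percentages, densities and bp.

## Synthetic scenarios

The generator emulates the statistical structure the analysis assumes, not
sequence-level biology. The recombination landscape is piecewise constant at
the marker spacing: baseline 1 cM/Mb, multiplied by 0.5 inside planted
domain-shaped valleys (40 domains of 100–400 kb across 2 × 20 Mb) and by 10
inside 2-kb hotspots placed at 10/Mb — a density and intensity chosen to
mimic the granular hotspot/coldspot texture of mammalian maps. Markers sit
every 500 bp. 400 links (1-bp anchors, distances 10–600 kb) are planted with
90% of spans fully inside valleys; CTCF motifs are placed outside domains so
the planted links are uninterrupted (a flag plants interrupting motifs for
filter tests). The `null` preset is identical except the valley multiplier
is 1 and links are placed uniformly: with no planted effect, placement
carries no information, and clustering many links into the same domains
would only create pseudo-replication among overlapping spans — the type-I
calibration of the paired test is checked under this preset.

Feature tracks are moving-average Gaussian fields on 1-kb bins (window 2
bins) scaled into realistic ranges (GC ≈ 0.41 ± 0.05, CpG ≈ 10/kb, SNP ≈
3/kb, PRDM9 ≈ 0.2/kb). GC fraction is normalized by its natural [0, 1]
bounds; the unbounded count densities by their observed range. Methylation
is generated per CpG (every ~200 bp) as
`μ + σ·(ρ·z_r + sqrt(1−ρ²)·z_s) + ε` clipped to [0, 1], where `z_r` is the
recombination rate smoothed to a 100-kb scale (methylation tracks
domain-scale structure, not individual hotspots) and `z_s` a smooth
confounder field, both standardized to unit variance at the 500-kb window
level so the realized window-level correlation approximates the configured
ρ (default −0.8; μ = 0.7, σ = 0.1, ε-sd = 0.05). The `mechanism` preset
(ρ = −1, no noise, no hotspots, 20-kb coupling scale) makes methylation
fully determine the landscape for the recapitulation analysis.

What the generator does **not** emulate: linkage disequilibrium, sequence
content, marker-density heterogeneity, chromosome-scale rate gradients,
telomere/centromere effects, or link-discovery biases. Passing tests
therefore demonstrate correctness and calibration of the procedures under
the stated structure, not robustness to every artefact of real maps.

## Predictor

The rate predictor is a random forest (500 trees, unlimited depth, fixed
seed, single-threaded) over per-interval features: chromosome index (a
categorical adjustment variable), interval length, per-link-type fraction of
the interval covered by merged link spans, and mean CpG methylation
(intervals without a CpG get the flag value −1). Evaluation is by pooled
out-of-fold predictions under chromosome-stratified 5-fold CV (folds
balanced within each chromosome), reporting Pearson r and MSE; the model is
then refit on all rows. The depletion-recapitulation fraction is
`(mean pred control − mean pred link) / (mean obs control − mean obs link)`,
reported raw plus [0, 1]-clipped.

## Numerical and design notes

* Exact signed-rank DP is O(n·Σ2r) and bit-stable; at n = 25 the null has
  2²⁵ assignments handled in float64 without loss.
* Permutation and label-permutation p-values carry the +1 correction and so
  never reach 0.
* Score polarity: p-value-like scores select minima (best-per-target,
  pruning order); O/E- or r-like scores select maxima (`top_fraction`).
  Thresholding by `max_p` is idempotent; `top_fraction` < 1 is by
  construction not (it always keeps ceil(f·n) of its current input).
* Pruning is greedy by ascending score with a 1-kb anchor-exclusion radius —
  a deterministic rule defined by this package for removing repeated counts
  of the same region.
* Local shifts draw one signed offset per link, shared by both anchors, so
  span length and distance class are preserved; shifts clip at chromosome
  bounds.
* Problem sizes in the shipped tests and the acceptance script (2 × 20 Mb
  genomes, 400 links, 200 calibration replicates, 2,000 predictor intervals)
  are the package's chosen desk-scale study conditions; every routine
  accepts larger inputs.

## Known limitations

The permutation universe requires both point sets as inputs; when absent the
model reports only the paired test. The k-d tree route is exact but
memory-bound at genome scale without subsampling. The paired test assumes
links are approximately independent — heavily overlapping links (e.g. many
links per domain) share landscape and inflate significance, which is
intrinsic to the paired design and is why the calibration check uses
non-clustered links.
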