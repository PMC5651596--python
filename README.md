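# recvalley

Statistical machinery for detecting **recombination-rate valleys** — regions
of significantly reduced meiotic recombination — within *gene regulatory
domains*: the genomic spans between regulatory elements and the genes they
control, as defined by eQTL/meQTL links, chromatin-conformation pairs (Hi-C,
ChIA-PET) or activity-correlation links. It is written for statistical
geneticists and regulatory genomicists who want to test whether a link set of
their own shows the same depletion, with controls matched the way the field
expects.

## The statistic

For a link with anchors `a`, `b` on one chromosome, the span is the hull
`[min(a,b), max(a,b))` and its average recombination rate is

    r(span) = (G(end) − G(start)) / (|span| / 1 Mb)   [cM/Mb]

where `G` is the cumulative genetic-map distance (cM), linearly interpolated
between markers. Links are stratified into three anchor-distance classes —
short (1–10 kb), intermediate (10–100 kb) and long (100 kb–1 Mb) — and each
class is tested twice:

* **paired rank test** — a two-sided Wilcoxon signed-rank test of per-link
  rates against *matched random controls* (same chromosome, exact same
  length; optionally matched on GC, CpG density, SNP density and PRDM9 motif
  density by rejection sampling at Euclidean tolerance 0.01 in normalized
  feature space, or via a k-d tree over all 1 kb–1 Mb candidate intervals);
* **median permutation test** — the observed median rate is ranked within
  10,000 medians of equally sized draws from the universe of all SNP×TSS
  point pairs in the same distance class, giving a one-sided depletion
  p-value `(1 + #{null ≤ obs}) / (1 + 10,000)`.

A class is flagged significant when both p-values reach the 1e-4 threshold.
The package also provides methylation–rate correlation scans (500-kb
windows), methylation-quantile rate profiles, a random-forest
recombination-rate predictor (chromosome, length, link-overlap fractions,
mean methylation) and the *depletion recapitulation* fraction — how much of
the observed link-vs-control rate difference the predictor reproduces.

Because real consortium data cannot ship with the package, a first-class
synthetic generator (`recvalley.simulate`) produces genomes with planted,
domain-shaped rate valleys, hotspot landscapes, matched feature tracks, and
a methylation track coupled to the domain-scale rate, so every procedure is
exercised end to end against known ground truth.

## Worked example

```python
import numpy as np
from recvalley import RecombinationValleyModel, make_scenario

sc = make_scenario("planted_valley", seed=1)   # 2×20 Mb, valleys at 0.5×
model = RecombinationValleyModel(
    sc.links, sc.gmap, sc.assembly,
    snp_positions=sc.snp_positions, tss_positions=sc.tss_positions,
)
res = model.fit(control_strategy="length", n_perm=10_000, seed=1)
print(res.summary())
```

```
Recombination rate valley test
  control strategy: length   alpha: 0.0001   n_perm: 10000
  paired test: two-sided Wilcoxon signed-rank (zero differences dropped)
  permutation test: one-sided depletion, +1 corrected

                n_links  mean_observed  mean_control  median_observed  median_control  paired_p    perm_p  significant
distance_class
MEDIUM              174         0.6161         1.018              0.5               1  6.79e-23 9.999e-05         True
LONG                226         0.6627         1.033            0.587           1.084 1.077e-31 9.999e-05         True
```

Reading: links of intermediate and long anchor distance average ~0.62–0.66
cM/Mb inside their spans versus ~1.02–1.03 cM/Mb in length-matched random
controls — the planted valleys (baseline 1 cM/Mb, multiplier 0.5) are
recovered — and both procedures reject far below the 1e-4 threshold. The
permutation p is the +1-corrected minimum `1/10001 ≈ 1e-4` because the
observed median ranks below all 10,000 null medians.

The same pipeline is scriptable from the shell:

```sh
recvalley simulate --preset planted_valley --seed 1 --out run/
recvalley test --config run/auto.yaml
recvalley methyl --config run/auto.yaml
recvalley report --config run/auto.yaml
```

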