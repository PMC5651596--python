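"""Significance procedures for the valley test.

Two complementary procedures, following the two comparators used for
regulatory links:

* a paired rank test (two-sided Wilcoxon signed-rank) of per-link rates
  against matched control rates — the "two-way paired" test against matched
  random intervals;
* a permutation test of the median rate against the null universe of all
  feasible point pairs (e.g. SNP x TSS) in the same distance class, with the
  +1-corrected one-sided depletion p-value.

The signed-rank null distribution is computed exactly (by dynamic
programming over signed midranks) up to n = 25 pairs and by the
tie-corrected normal approximation above that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .controls import NullPairUniverse
from .genome import DistanceClass, Link
from .recomb import GeneticMap, interval_rates, link_rates

__all__ = [
    "PairedRankResult",
    "paired_rank_test",
    "PermutationResult",
    "permutation_median_test",
    "EXACT_N_MAX",
]

EXACT_N_MAX = 25


@dataclass(frozen=True)
class PairedRankResult:
    statistic: float  # W+ - W- (signed; negates when the vectors are swapped)
    pvalue: float
    n_effective: int
    method: str  # "exact" | "normal" | "degenerate"


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all 2^n sign assignments of the (mid)ranks."""
    r2 = np.rint(2 * ranks).astype(np.int64)  # doubled ranks are integers even with ties
    m2 = int(r2.sum())
    counts = np.zeros(m2 + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    total = 2.0 ** len(r2)
    w2 = int(np.rint(2 * w_plus))
    w2 = min(w2, m2 - w2)  # smaller tail; the null is symmetric under sign flips
    cum = np.cumsum(counts)
    lower = cum[w2]
    upper = total - (cum[m2 - w2 - 1] if m2 - w2 - 1 >= 0 else 0.0)
    return min(1.0, (lower + upper) / total)


def paired_rank_test(
    observed: Sequence[float], control: Sequence[float]
) -> PairedRankResult:
    """Two-sided Wilcoxon signed-rank test on paired rate differences.

    Zero differences are dropped (the classical convention), ties get
    midranks.  Returns p = 1 with a degenerate flag when every pair is tied.
    """
    observed = np.asarray(observed, dtype=float)
    control = np.asarray(control, dtype=float)
    if observed.shape != control.shape or observed.ndim != 1 or observed.size < 1:
        raise ValueError("observed and control must be equal-length 1-d vectors, n >= 1")
    d = observed - control
    d = d[d != 0]
    n = d.size
    if n == 0:
        return PairedRankResult(0.0, 1.0, 0, "degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = w_plus - w_minus
    if n <= EXACT_N_MAX:
        p = _exact_signed_rank_p(ranks, w_plus)
        return PairedRankResult(statistic, p, n, "exact")
    mu = n * (n + 1) / 4.0
    tie_term = 0.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0:
        return PairedRankResult(statistic, 1.0, n, "degenerate")
    # continuity correction toward the mean
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return PairedRankResult(statistic, max(p, np.nextafter(0.0, 1.0)), n, "normal")


@dataclass(frozen=True)
class PermutationResult:
    observed_median: float
    pvalue: float  # one-sided for depletion, +1 corrected
    n_links: int
    n_perm: int
    null_median_mean: float
    null_median_sd: float


def permutation_median_test(
    links: Sequence[Link],
    gmap: GeneticMap,
    points_a: dict[str, np.ndarray],
    points_b: dict[str, np.ndarray],
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict[DistanceClass, PermutationResult]:
    """Permutation test of the median rate against the null pair universe.

    Per distance class: the observed median of link rates is ranked within
    the null distribution of medians of equally sized draws of random point
    pairs from the same class; the one-sided depletion p-value is
    ``(1 + #{null <= observed}) / (1 + n_perm)``.  Classes without links are
    skipped.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng or np.random.default_rng()
    by_class: dict[DistanceClass, list[Link]] = {}
    for ln in links:
        by_class.setdefault(ln.distance_class, []).append(ln)
    out: dict[DistanceClass, PermutationResult] = {}
    for cls, cls_links in by_class.items():
        if cls == DistanceClass.EXCLUDED or not cls_links:
            continue
        n = len(cls_links)
        observed = float(np.median(link_rates(cls_links, gmap)))
        uni = NullPairUniverse(points_a, points_b, cls)
        ci, pa, pb = uni.sample_arrays(n_perm * n, rng)
        rates = np.empty(n_perm * n)
        starts = np.minimum(pa, pb)
        ends = np.maximum(pa, pb) + 1
        names = uni.chrom_names
        for c in np.unique(ci):
            m = ci == c
            rates[m] = interval_rates(gmap, names[c], starts[m], ends[m])
        null_medians = np.median(rates.reshape(n_perm, n), axis=1)
        p = (1 + int((null_medians <= observed).sum())) / (1 + n_perm)
        out[cls] = PermutationResult(
            observed_median=observed,
            pvalue=p,
            n_links=n,
            n_perm=n_perm,
            null_median_mean=float(null_medians.mean()),
            null_median_sd=float(null_medians.std(ddof=1)) if n_perm > 1 else 0.0,
        )
    return out
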