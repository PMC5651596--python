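"""Recombination-rate computation from a genetic map.

A genetic map is a monotone mapping from physical position (bp) to cumulative
genetic distance (cM); the average recombination rate of an interval is the
genetic distance it spans divided by its physical length in Mb.  Cumulative
cM is linearly interpolated between markers and clamped to the terminal
values outside the marker range, so intervals with no map coverage get a
rate of exactly 0 (flagged separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import (
    DISTANCE_CLASS_BOUNDS,
    DistanceClass,
    GenomeAssembly,
    GenomicInterval,
    Link,
)
from .tracks import FeatureTrack

__all__ = [
    "GeneticMap",
    "cumulative_cm_at",
    "interval_rate",
    "interval_rates",
    "interval_rate_masked",
    "link_rates",
    "mean_rate_by_distance",
    "hotspot_density",
    "rate_track",
]


@dataclass
class GeneticMap:
    """Per-chromosome marker positions (bp) with cumulative genetic distance (cM)."""

    positions: dict[str, np.ndarray]
    cum_cm: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom in self.positions:
            pos = np.asarray(self.positions[chrom], dtype=np.int64)
            cm = np.asarray(self.cum_cm[chrom], dtype=float)
            if pos.shape != cm.shape or pos.size < 2:
                raise ValueError(f"map on {chrom}: need >= 2 equal-length marker arrays")
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"map on {chrom}: positions not strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"map on {chrom}: cumulative cM decreases")
            self.positions[chrom] = pos
            self.cum_cm[chrom] = cm

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.positions

    def marker_rates(self, chrom: str) -> np.ndarray:
        """Per-marker-interval rate in cM/Mb (piecewise-constant representation)."""
        pos = self.positions[chrom]
        cm = self.cum_cm[chrom]
        return np.diff(cm) / (np.diff(pos) / 1e6)


def cumulative_cm_at(gmap: GeneticMap, chrom: str, pos) -> float | np.ndarray:
    """Cumulative cM at *pos*, linearly interpolated between flanking markers.

    Positions outside the marker range clamp to the terminal cumulative value.
    """
    if chrom not in gmap:
        raise KeyError(f"chromosome {chrom!r} not in genetic map")
    out = np.interp(np.asarray(pos, dtype=float), gmap.positions[chrom], gmap.cum_cm[chrom])
    return float(out) if np.isscalar(pos) else out


def interval_rates(gmap: GeneticMap, chrom: str, starts, ends) -> np.ndarray:
    """Vectorized average rate (cM/Mb) for intervals [starts, ends) on one chromosome."""
    starts = np.asarray(starts, dtype=float)
    ends = np.asarray(ends, dtype=float)
    dcm = cumulative_cm_at(gmap, chrom, ends) - cumulative_cm_at(gmap, chrom, starts)
    return dcm / ((ends - starts) / 1e6)


def interval_rate(gmap: GeneticMap, interval: GenomicInterval) -> tuple[float, bool]:
    """Average recombination rate of one interval.

    Returns ``(rate_cM_per_Mb, covered)``; *covered* is False when the
    interval lies entirely outside the marker range (rate is then 0).
    """
    pos = gmap.positions[interval.chrom]
    covered = not (interval.end <= pos[0] or interval.start >= pos[-1])
    rate = float(interval_rates(gmap, interval.chrom, [interval.start], [interval.end])[0])
    return rate, covered


def interval_rate_masked(
    gmap: GeneticMap,
    interval: GenomicInterval,
    mask_intervals: Sequence[GenomicInterval],
) -> float:
    """Average rate over the unmasked portion of *interval*.

    *mask_intervals* are excluded (e.g. gene bodies padded by 2 kb when
    restricting to intergenic sequence).  Returns NaN when the mask covers
    the interval completely.
    """
    segs = [(interval.start, interval.end)]
    for m in mask_intervals:
        if m.chrom != interval.chrom:
            continue
        nxt = []
        for s, e in segs:
            if m.end <= s or m.start >= e:
                nxt.append((s, e))
                continue
            if s < m.start:
                nxt.append((s, m.start))
            if m.end < e:
                nxt.append((m.end, e))
        segs = nxt
    if not segs:
        return float("nan")
    starts = np.array([s for s, _ in segs], dtype=float)
    ends = np.array([e for _, e in segs], dtype=float)
    dcm = (
        cumulative_cm_at(gmap, interval.chrom, ends)
        - cumulative_cm_at(gmap, interval.chrom, starts)
    ).sum()
    total = (ends - starts).sum()
    return float(dcm / (total / 1e6))


def link_rates(links: Sequence[Link], gmap: GeneticMap) -> np.ndarray:
    """Average rate over each link's span (anchor hull), vectorized per chromosome."""
    out = np.empty(len(links))
    by_chrom: dict[str, list[int]] = {}
    for i, ln in enumerate(links):
        by_chrom.setdefault(ln.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        starts = np.array([links[i].span.start for i in idx], dtype=float)
        ends = np.array([links[i].span.end for i in idx], dtype=float)
        out[idx] = interval_rates(gmap, chrom, starts, ends)
    return out


def mean_rate_by_distance(
    links: Sequence[Link], gmap: GeneticMap, n_bins: int = 100
) -> pd.DataFrame:
    """Mean rate vs anchor distance, binned within each distance class.

    The confidence half-width follows the convention ``sd * 1.96 / 10`` with
    the sample standard deviation (ddof=1, defined as 0 for n <= 1).
    Empty bins are emitted with n=0 and a missing mean.
    """
    if not links:
        raise ValueError("links must be non-empty")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rates = link_rates(links, gmap)
    dists = np.array([ln.distance for ln in links])
    rows = []
    for cls_name, (lo, hi) in DISTANCE_CLASS_BOUNDS.items():
        edges = np.linspace(lo, hi, n_bins + 1)
        if cls_name == "LONG":
            in_cls = (dists >= lo) & (dists <= hi)
        else:
            in_cls = (dists >= lo) & (dists < hi)
        which = np.clip(np.digitize(dists, edges) - 1, 0, n_bins - 1)
        for b in range(n_bins):
            sel = in_cls & (which == b)
            n = int(sel.sum())
            if n == 0:
                mean = np.nan
                half = np.nan
            else:
                mean = float(rates[sel].mean())
                sd = float(rates[sel].std(ddof=1)) if n > 1 else 0.0
                half = sd * 1.96 / 10.0
            rows.append(
                {
                    "distance_class": cls_name,
                    "bin_lo": edges[b],
                    "bin_hi": edges[b + 1],
                    "n": n,
                    "mean_rate": mean,
                    "ci_halfwidth": half,
                }
            )
    return pd.DataFrame(rows)


def hotspot_density(interval: GenomicInterval, hotspots: Sequence[GenomicInterval]) -> float:
    """Hotspots per kb: count of hotspot midpoints inside *interval* / length (kb)."""
    count = sum(
        1
        for h in hotspots
        if h.chrom == interval.chrom and interval.start <= h.midpoint < interval.end
    )
    return count / (interval.length / 1_000.0)


def rate_track(gmap: GeneticMap, assembly: GenomeAssembly, bin_size: int = 1_000) -> FeatureTrack:
    """Project the genetic map onto a binned rate track (cM/Mb per bin)."""
    values = {}
    for chrom, length in assembly.chromosomes:
        if chrom not in gmap:
            continue
        n = int(np.ceil(length / bin_size))
        starts = np.arange(n, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, length)
        values[chrom] = interval_rates(gmap, chrom, starts, ends)
    return FeatureTrack("recombination_rate", bin_size, values)
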