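"""Matched-control interval generators and the null-pair sampler.

Four control strategies for a query link span:

* length-matched: uniform random interval of the same length on the same
  chromosome;
* feature-matched by rejection: repeat length-matched draws until the
  Euclidean distance in normalized feature space (GC, CpG density, SNP
  density, PRDM9 motif density, ...) drops below a tolerance (default 0.01)
  or an iteration budget (default 10,000) is exhausted;
* feature-matched by k-d tree: enumerate candidate intervals on a grid
  (lengths 1 kb-1 Mb in 1-kb steps), index their feature vectors, query the
  k = 1000 nearest neighbours, filter near-self and CTCF-containing
  candidates, and pick one at random;
* domain-constrained: uniform same-length interval inside the chromatin
  domain containing the link.

Separately, :class:`NullPairUniverse` samples uniformly from the implicit
universe of all same-chromosome point pairs (e.g. array SNP x TSS) whose
distance falls in a distance class, without materializing the cross product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .genome import (
    DISTANCE_CLASS_BOUNDS,
    DistanceClass,
    GenomeAssembly,
    GenomicInterval,
    Link,
)
from .tracks import FeatureTrack

logger = logging.getLogger(__name__)

__all__ = [
    "ControlPair",
    "ControlSet",
    "sample_length_matched",
    "sample_feature_matched_rejection",
    "CandidateIndex",
    "build_candidate_index",
    "sample_kdtree_matched",
    "sample_within_domain",
    "NullPairUniverse",
    "sample_null_pairs",
]


@dataclass(frozen=True)
class ControlPair:
    link: Link
    control: GenomicInterval
    feature_distance: float
    iterations: int
    matched: bool


@dataclass
class ControlSet:
    pairs: list[ControlPair]

    def __post_init__(self) -> None:
        for p in self.pairs:
            if p.control.chrom != p.link.chrom:
                raise ValueError("control on a different chromosome than its link")
            if p.control.length != p.link.span.length:
                raise ValueError("control length differs from link span length")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def match_fraction(self) -> float:
        if not self.pairs:
            return float("nan")
        return sum(p.matched for p in self.pairs) / len(self.pairs)


def sample_length_matched(
    link: Link, assembly: GenomeAssembly, rng: np.random.Generator
) -> GenomicInterval:
    """Uniform random interval with the link span's exact length and chromosome."""
    span = link.span
    chrom_len = assembly.length(link.chrom)
    if span.length > chrom_len:
        raise ValueError(
            f"link span length {span.length} exceeds chromosome {link.chrom} ({chrom_len})"
        )
    start = int(rng.integers(0, chrom_len - span.length + 1))
    return GenomicInterval(link.chrom, start, start + span.length)


def _feature_vector(
    tracks: Sequence[FeatureTrack], chrom: str, starts, ends
) -> np.ndarray:
    """Normalized feature matrix, one row per interval, one column per track."""
    cols = [np.atleast_1d(t.normalized_interval_mean(chrom, starts, ends)) for t in tracks]
    return np.column_stack(cols)


def sample_feature_matched_rejection(
    link: Link,
    tracks: Sequence[FeatureTrack],
    assembly: GenomeAssembly,
    rng: np.random.Generator,
    tolerance: float = 0.01,
    max_iter: int = 10_000,
    batch: int = 1_024,
) -> ControlPair:
    """Rejection-sample a length-matched control with matched features.

    Draws are accepted when the Euclidean distance between the normalized
    feature vectors of the link span and the candidate falls below
    *tolerance*; on exhaustion the best candidate seen is returned with
    ``matched=False``.
    """
    if tolerance <= 0 and max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    span = link.span
    chrom_len = assembly.length(link.chrom)
    if not tracks:
        logger.warning("no feature tracks supplied; degrading to pure length matching")
        ctrl = sample_length_matched(link, assembly, rng)
        return ControlPair(link, ctrl, 0.0, 1, True)
    target = _feature_vector(tracks, link.chrom, span.start, span.end)[0]
    best_dist = np.inf
    best_start = 0
    done = 0
    while done < max_iter:
        m = min(batch, max_iter - done)
        starts = rng.integers(0, chrom_len - span.length + 1, size=m)
        feats = _feature_vector(tracks, link.chrom, starts, starts + span.length)
        dists = np.sqrt(((feats - target) ** 2).sum(axis=1))
        hits = np.nonzero(dists < tolerance)[0]
        if hits.size:
            i = int(hits[0])
            ctrl = GenomicInterval(link.chrom, int(starts[i]), int(starts[i]) + span.length)
            return ControlPair(link, ctrl, float(dists[i]), done + i + 1, True)
        i = int(np.argmin(dists))
        if dists[i] < best_dist:
            best_dist = float(dists[i])
            best_start = int(starts[i])
        done += m
    ctrl = GenomicInterval(link.chrom, best_start, best_start + span.length)
    return ControlPair(link, ctrl, best_dist, max_iter, False)


# ------------------------------------------------------------ k-d tree route

@dataclass
class CandidateIndex:
    """Enumerated candidate intervals with a k-d tree over their features.

    Chromosome index and interval length are themselves matching features,
    min-max normalized like the track features.
    """

    assembly: GenomeAssembly
    tracks: tuple[FeatureTrack, ...]
    chrom_ids: np.ndarray  # per candidate, index into assembly.chromosomes
    starts: np.ndarray
    lengths: np.ndarray
    features: np.ndarray
    feature_mins: np.ndarray
    feature_maxs: np.ndarray
    tree: cKDTree

    @property
    def n_candidates(self) -> int:
        return len(self.starts)

    def link_features(self, link: Link) -> np.ndarray:
        span = link.span
        raw = np.concatenate(
            (
                [float(self.assembly.chrom_index(link.chrom)), float(span.length)],
                _feature_vector(self.tracks, link.chrom, span.start, span.end)[0]
                if self.tracks
                else [],
            )
        )
        rng_ = np.maximum(self.feature_maxs - self.feature_mins, 1e-300)
        return (raw - self.feature_mins) / rng_


def build_candidate_index(
    assembly: GenomeAssembly,
    tracks: Sequence[FeatureTrack],
    grid: int = 1_000,
    length_min: int = 1_000,
    length_max: int = 1_000_000,
    length_step: int = 1_000,
    max_candidates: int = 2_000_000,
    subsample: int | None = None,
) -> CandidateIndex:
    """Enumerate grid candidates of all lengths and index their feature vectors.

    Genome-scale enumeration is intractable exhaustively; set *subsample* to
    keep every n-th candidate when the count would exceed *max_candidates*.
    """
    if grid < 1 or length_step < 1:
        raise ValueError("grid and length_step must be >= 1")
    lengths_all = np.arange(length_min, length_max + 1, length_step, dtype=np.int64)
    total = 0
    for chrom, L in assembly.chromosomes:
        feas = lengths_all[lengths_all <= L]
        total += int(((L - feas) // grid + 1).sum())
    stride = subsample or 1
    if total // stride > max_candidates:
        raise MemoryError(
            f"{total // stride} candidates exceed the cap of {max_candidates}; "
            "set a larger `subsample` factor or raise `max_candidates`"
        )
    chrom_ids, starts, lens = [], [], []
    offset = 0  # global stride phase so subsampling stays uniform across blocks
    for ci, (chrom, L) in enumerate(assembly.chromosomes):
        for ell in lengths_all[lengths_all <= L]:
            n = (L - ell) // grid + 1
            idx = np.arange((stride - offset) % stride, n, stride, dtype=np.int64)
            offset = (offset + n) % stride
            if idx.size == 0:
                continue
            starts.append(idx * grid)
            lens.append(np.full(idx.size, ell, dtype=np.int64))
            chrom_ids.append(np.full(idx.size, ci, dtype=np.int32))
    chrom_ids = np.concatenate(chrom_ids)
    starts = np.concatenate(starts)
    lens = np.concatenate(lens)

    cols = [chrom_ids.astype(float), lens.astype(float)]
    for t in tracks:
        col = np.empty(len(starts))
        for ci, (chrom, _) in enumerate(assembly.chromosomes):
            m = chrom_ids == ci
            if m.any():
                col[m] = t.normalized_interval_mean(chrom, starts[m], starts[m] + lens[m])
        cols.append(col)
    raw = np.column_stack(cols)
    mins = raw.min(axis=0)
    maxs = raw.max(axis=0)
    # track columns are already in normalized units; renormalizing them over the
    # candidate set keeps every axis on a comparable [0, 1] scale
    rng_ = np.maximum(maxs - mins, 1e-300)
    feats = (raw - mins) / rng_
    return CandidateIndex(
        assembly=assembly,
        tracks=tuple(tracks),
        chrom_ids=chrom_ids,
        starts=starts,
        lengths=lens,
        features=feats,
        feature_mins=mins,
        feature_maxs=maxs,
        tree=cKDTree(feats),
    )


def _overlaps_any(
    starts: np.ndarray, cummax_ends: np.ndarray, s: int, e: int
) -> bool:
    i = np.searchsorted(starts, e, side="left")
    return i > 0 and cummax_ends[i - 1] > s


def sample_kdtree_matched(
    index: CandidateIndex,
    link: Link,
    rng: np.random.Generator,
    k: int = 1_000,
    ctcf_motifs: Sequence[GenomicInterval] | None = None,
    min_distance: int = 1_000,
    max_overlap: float = 0.5,
    k_cap_factor: int = 8,
) -> GenomicInterval:
    """Pick a control uniformly among the k nearest feature-matched candidates.

    Candidates within *min_distance* of the link span, or overlapping it by
    more than *max_overlap* of the shorter interval, are dropped (avoids
    re-sampling the link's own position); with CTCF motifs supplied,
    candidates overlapping a motif are dropped too.  If every candidate is
    filtered the search widens to 2k, 4k, ... up to *k_cap_factor* x k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    span = link.span
    motif_idx = None
    if ctcf_motifs:
        per = {}
        for chrom in {m.chrom for m in ctcf_motifs}:
            ms = sorted((m for m in ctcf_motifs if m.chrom == chrom), key=lambda m: m.start)
            s = np.array([m.start for m in ms], dtype=np.int64)
            e = np.maximum.accumulate(np.array([m.end for m in ms], dtype=np.int64))
            per[chrom] = (s, e)
        motif_idx = per
    q = index.link_features(link)
    link_ci = index.assembly.chrom_index(link.chrom)
    kk = min(k, index.n_candidates)
    while True:
        _, nn = index.tree.query(q, k=kk)
        nn = np.atleast_1d(nn)
        keep = []
        for j in nn:
            s, e = int(index.starts[j]), int(index.starts[j] + index.lengths[j])
            if index.chrom_ids[j] == link_ci:
                ov = max(0, min(e, span.end) - max(s, span.start))
                if ov > 0:
                    if ov > max_overlap * min(e - s, span.length):
                        continue
                elif max(s, span.start) - min(e, span.end) < min_distance:
                    continue
            if motif_idx is not None:
                chrom = index.assembly.chromosomes[index.chrom_ids[j]][0]
                if chrom in motif_idx and _overlaps_any(*motif_idx[chrom], s, e):
                    continue
            keep.append(j)
        if keep:
            j = keep[int(rng.integers(0, len(keep)))]
            chrom = index.assembly.chromosomes[index.chrom_ids[j]][0]
            return GenomicInterval(chrom, int(index.starts[j]), int(index.starts[j] + index.lengths[j]))
        if kk >= min(k * k_cap_factor, index.n_candidates):
            raise RuntimeError(
                f"all {kk} nearest candidates filtered for link at "
                f"{span.chrom}:{span.start}-{span.end}"
            )
        kk = min(kk * 2, k * k_cap_factor, index.n_candidates)


def sample_within_domain(
    link: Link, domains: Sequence[GenomicInterval], rng: np.random.Generator
) -> GenomicInterval | None:
    """Uniform same-length interval inside the domain containing the link span.

    Ties (nested domains) break to the smallest containing domain.  Returns
    None (with a warning) when no domain contains the span.
    """
    span = link.span
    containing = [d for d in domains if d.contains(span)]
    if not containing:
        logger.warning(
            "link span %s:%d-%d not contained in any domain; skipped",
            span.chrom, span.start, span.end,
        )
        return None
    dom = min(containing, key=lambda d: d.length)
    start = int(rng.integers(dom.start, dom.end - span.length + 1))
    return GenomicInterval(span.chrom, start, start + span.length)


# ------------------------------------------------------------ null pair universe

class NullPairUniverse:
    """Uniform sampler over same-chromosome point pairs in a distance class.

    *points_a* and *points_b* are per-chromosome sorted position arrays
    (e.g. genotyping-array SNPs and TSSs).  The universe of feasible pairs is
    never materialized: per a-point the feasible b-range is located by binary
    search, and flat sample indices are mapped back by arithmetic.
    """

    def __init__(
        self,
        points_a: dict[str, np.ndarray],
        points_b: dict[str, np.ndarray],
        distance_class: DistanceClass,
    ) -> None:
        if distance_class == DistanceClass.EXCLUDED:
            raise ValueError("cannot build a universe for the EXCLUDED class")
        lo, hi = DISTANCE_CLASS_BOUNDS[distance_class.value]
        inclusive = distance_class == DistanceClass.LONG
        self.distance_class = distance_class
        self._chroms: list[str] = []
        self._a: list[np.ndarray] = []
        self._b: list[np.ndarray] = []
        self._bounds: list[np.ndarray] = []  # per chrom: columns rlo, rhi, llo, lhi
        counts = []
        for chrom in sorted(set(points_a) & set(points_b)):
            a = np.sort(np.asarray(points_a[chrom], dtype=np.int64))
            b = np.sort(np.asarray(points_b[chrom], dtype=np.int64))
            if a.size == 0 or b.size == 0:
                continue
            rlo = np.searchsorted(b, a + lo, side="left")
            rhi = np.searchsorted(b, a + hi, side="right" if inclusive else "left")
            llo = np.searchsorted(b, a - hi, side="left" if inclusive else "right")
            lhi = np.searchsorted(b, a - lo, side="right")
            cnt = (rhi - rlo) + (lhi - llo)
            self._chroms.append(chrom)
            self._a.append(a)
            self._b.append(b)
            self._bounds.append(np.column_stack((rlo, rhi, llo, lhi)))
            counts.append(cnt)
        if not counts or sum(int(c.sum()) for c in counts) == 0:
            raise ValueError(f"no feasible pair in distance class {distance_class.value}")
        self._row_chrom = np.concatenate(
            [np.full(len(c), i, dtype=np.int32) for i, c in enumerate(counts)]
        )
        self._row_a_idx = np.concatenate([np.arange(len(c)) for c in counts])
        flat = np.concatenate(counts)
        self._cum = np.cumsum(flat)
        self._flat_counts = flat
        self.total_pairs = int(self._cum[-1])

    def sample_arrays(
        self, n: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """n uniform pairs as (chrom_index, pos_a, pos_b) arrays (vectorized)."""
        u = rng.integers(0, self.total_pairs, size=n)
        rows = np.searchsorted(self._cum, u, side="right")
        off = u - (self._cum[rows] - self._flat_counts[rows])
        ci = self._row_chrom[rows]
        ai = self._row_a_idx[rows]
        pa = np.empty(n, dtype=np.int64)
        pb = np.empty(n, dtype=np.int64)
        for c in np.unique(ci):
            m = ci == c
            bnd = self._bounds[c][ai[m]]
            rcnt = bnd[:, 1] - bnd[:, 0]
            o = off[m]
            bi = np.where(o < rcnt, bnd[:, 0] + o, bnd[:, 2] + (o - rcnt))
            pa[m] = self._a[c][ai[m]]
            pb[m] = self._b[c][bi]
        return ci, pa, pb

    @property
    def chrom_names(self) -> list[str]:
        return list(self._chroms)

    def sample(self, n: int, rng: np.random.Generator) -> list[tuple[str, int, int]]:
        """n pairs (chrom, pos_a, pos_b) uniform over the feasible universe."""
        ci, pa, pb = self.sample_arrays(n, rng)
        return [(self._chroms[c], int(a), int(b)) for c, a, b in zip(ci, pa, pb)]

    def enumerate_pairs(self) -> list[tuple[str, int, int]]:
        """All feasible pairs (test oracle; only for small universes)."""
        out = []
        for ci, chrom in enumerate(self._chroms):
            a, b = self._a[ci], self._b[ci]
            for ai, (rlo, rhi, llo, lhi) in enumerate(self._bounds[ci]):
                for bi in range(rlo, rhi):
                    out.append((chrom, int(a[ai]), int(b[bi])))
                for bi in range(llo, lhi):
                    out.append((chrom, int(a[ai]), int(b[bi])))
        return out


def sample_null_pairs(
    points_a: dict[str, np.ndarray],
    points_b: dict[str, np.ndarray],
    n: int,
    distance_class: DistanceClass,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Sample n null point pairs in a distance class, returned as hull intervals."""
    uni = NullPairUniverse(points_a, points_b, distance_class)
    return [
        GenomicInterval(chrom, min(pa, pb), max(pa, pb) + 1)
        for chrom, pa, pb in uni.sample(n, rng)
    ]
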