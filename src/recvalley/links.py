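"""Link-set hygiene and stratification.

Operations that clean or stratify regulatory link sets before the valley
test: CTCF-interruption filtering, best-link-per-target selection, spatial
pruning, score thresholding, local random shifts, constitutive/specific
classification across tissues, and correlation-based activity-link
prediction between peak signal and gene expression.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left
from typing import Sequence

import numpy as np

from .genome import GenomeAssembly, GenomicInterval, Link, LinkType

logger = logging.getLogger(__name__)

__all__ = [
    "filter_ctcf_uninterrupted",
    "select_best_per_target",
    "prune_overlapping",
    "threshold_links",
    "shift_links",
    "classify_constitutive",
    "predict_activity_links",
]


def _ordered_anchors(link: Link) -> tuple[GenomicInterval, GenomicInterval]:
    a, b = link.anchor_a, link.anchor_b
    return (a, b) if a.start <= b.start else (b, a)


def filter_ctcf_uninterrupted(
    links: Sequence[Link], ctcf_motifs: Sequence[GenomicInterval]
) -> tuple[list[Link], list[Link]]:
    """Partition links into (uninterrupted, interrupted) by CTCF motifs.

    A link is interrupted iff at least one motif lies entirely inside the
    open gap between its two anchors; a motif overlapping an anchor itself
    does not interrupt.  Interruption is taken as evidence the two elements
    sit in different chromatin loops.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {m.chrom for m in ctcf_motifs}:
        ms = sorted((m for m in ctcf_motifs if m.chrom == chrom), key=lambda m: m.start)
        by_chrom[chrom] = (
            np.array([m.start for m in ms], dtype=np.int64),
            np.array([m.end for m in ms], dtype=np.int64),
        )
    uninterrupted, interrupted = [], []
    for ln in links:
        left, right = _ordered_anchors(ln)
        hit = False
        if ln.chrom in by_chrom and right.start > left.end:
            starts, ends = by_chrom[ln.chrom]
            lo = np.searchsorted(starts, left.end, side="left")
            hi = np.searchsorted(starts, right.start, side="left")
            if hi > lo:
                hit = bool(ends[lo:hi].min() <= right.start)
        (interrupted if hit else uninterrupted).append(ln)
    return uninterrupted, interrupted


def select_best_per_target(links: Sequence[Link]) -> list[Link]:
    """Keep only the most significant link (minimum p) per target gene/CpG.

    Ties break to the shorter anchor distance, then to the leftmost anchor.
    Links without a target id are dropped with a warning.
    """
    best: dict[str, Link] = {}
    n_dropped = 0
    for ln in links:
        if ln.target_id is None:
            n_dropped += 1
            continue
        key = (ln.score, ln.distance, min(ln.anchor_a.start, ln.anchor_b.start))
        cur = best.get(ln.target_id)
        if cur is None or key < (
            cur.score,
            cur.distance,
            min(cur.anchor_a.start, cur.anchor_b.start),
        ):
            best[ln.target_id] = ln
    if n_dropped:
        logger.warning("select_best_per_target: dropped %d links without target_id", n_dropped)
    return list(best.values())


def prune_overlapping(links: Sequence[Link], exclusion_radius: int = 1_000) -> list[Link]:
    """Greedy spatial pruning to remove repeated counts of the same region.

    Links are visited in order of ascending score (most significant first);
    a link is rejected when either of its anchors lies within
    *exclusion_radius* of any already-accepted anchor.
    """
    order = sorted(
        links,
        key=lambda ln: (ln.score, ln.distance, min(ln.anchor_a.start, ln.anchor_b.start)),
    )
    accepted: list[Link] = []
    anchors: dict[str, list[float]] = {}

    def near(chrom: str, mid: float) -> bool:
        arr = anchors.get(chrom, [])
        i = bisect_left(arr, mid)
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(arr[j] - mid) <= exclusion_radius:
                return True
        return False

    for ln in order:
        mids = (ln.anchor_a.midpoint, ln.anchor_b.midpoint)
        if any(near(ln.chrom, m) for m in mids):
            continue
        accepted.append(ln)
        arr = anchors.setdefault(ln.chrom, [])
        for m in mids:
            arr.insert(bisect_left(arr, m), m)
    return accepted


def threshold_links(links: Sequence[Link], mode: str, value: float) -> list[Link]:
    """Subset a link set by score.

    ``top_fraction``: keep the ceil(fraction * n) highest-scoring links
    (e.g. Hi-C observed/expected).  ``max_p``: keep links with score <= value
    (p-value polarity).
    """
    if mode == "top_fraction":
        if not (0 < value <= 1):
            raise ValueError("top_fraction value must be in (0, 1]")
        k = math.ceil(value * len(links))
        order = sorted(
            links,
            key=lambda ln: (-ln.score, ln.distance, min(ln.anchor_a.start, ln.anchor_b.start)),
        )
        return order[:k]
    if mode == "max_p":
        return [ln for ln in links if ln.score <= value]
    raise ValueError(f"unknown threshold mode {mode!r}")


def shift_links(
    links: Sequence[Link],
    min_shift: int,
    max_shift: int,
    rng: np.random.Generator,
    assembly: GenomeAssembly | None = None,
) -> list[Link]:
    """Translate each link by one signed offset shared by both anchors.

    The offset magnitude is uniform on [min_shift, max_shift] (defaults in
    the pipeline: 1-5 kb) with a random sign, preserving span length and
    distance class; shifts are clipped so anchors stay inside the chromosome.
    Used as a local-background comparator around the best genetic links.
    """
    if not (0 < min_shift <= max_shift):
        raise ValueError("require 0 < min_shift <= max_shift")
    out = []
    for ln in links:
        mag = rng.uniform(min_shift, max_shift)
        off = int(round(mag)) * (1 if rng.random() < 0.5 else -1)
        if assembly is not None:
            lo = min(ln.anchor_a.start, ln.anchor_b.start)
            hi = max(ln.anchor_a.end, ln.anchor_b.end)
            L = assembly.length(ln.chrom)
            off = max(-lo, min(off, L - hi))
        out.append(
            Link(
                GenomicInterval(ln.chrom, ln.anchor_a.start + off, ln.anchor_a.end + off),
                GenomicInterval(ln.chrom, ln.anchor_b.start + off, ln.anchor_b.end + off),
                link_type=ln.link_type,
                score=ln.score,
                target_id=ln.target_id,
            )
        )
    return out


def classify_constitutive(
    linksets_by_tissue: dict[str, Sequence[Link]],
    min_tissues: int | None = None,
    anchor_tolerance: int = 1_000,
) -> tuple[list[Link], list[Link]]:
    """Partition the union of per-tissue link sets into (constitutive, specific).

    A link is constitutive when a link with both anchor midpoints within
    *anchor_tolerance* exists in at least *min_tissues* tissue sets
    (default: all of them).  Anchors are compared in genomic order, so the
    A/B labelling of a link does not matter.
    """
    if len(linksets_by_tissue) < 2:
        raise ValueError("need at least 2 tissue link sets")
    if min_tissues is None:
        min_tissues = len(linksets_by_tissue)
    index: dict[str, dict[str, np.ndarray]] = {}
    for tissue, links in linksets_by_tissue.items():
        per: dict[str, list[tuple[float, float]]] = {}
        for ln in links:
            left, right = _ordered_anchors(ln)
            per.setdefault(ln.chrom, []).append((left.midpoint, right.midpoint))
        index[tissue] = {
            c: np.array(sorted(v), dtype=float).reshape(-1, 2) for c, v in per.items()
        }

    def present(tissue: str, chrom: str, ma: float, mb: float) -> bool:
        arr = index[tissue].get(chrom)
        if arr is None:
            return False
        lo = np.searchsorted(arr[:, 0], ma - anchor_tolerance, side="left")
        hi = np.searchsorted(arr[:, 0], ma + anchor_tolerance, side="right")
        return bool(np.any(np.abs(arr[lo:hi, 1] - mb) <= anchor_tolerance))

    constitutive, specific = [], []
    for links in linksets_by_tissue.values():
        for ln in links:
            left, right = _ordered_anchors(ln)
            n = sum(
                present(t, ln.chrom, left.midpoint, right.midpoint) for t in linksets_by_tissue
            )
            (constitutive if n >= min_tissues else specific).append(ln)
    return constitutive, specific


def predict_activity_links(
    peaks: Sequence[GenomicInterval],
    peak_signal: np.ndarray,
    tss: Sequence[tuple[str, int, str]],
    expression: np.ndarray,
    max_distance: int = 1_000_000,
    r_threshold: float = 0.7,
) -> list[Link]:
    """Predict enhancer-gene links by signal/expression correlation.

    For every peak-gene pair with |peak midpoint - TSS| <= *max_distance* on
    the same chromosome, the Pearson correlation of peak signal and gene
    expression across cell types is computed; pairs with r >= *r_threshold*
    become links (score = r).  Zero-variance rows are skipped with a warning.
    """
    peak_signal = np.asarray(peak_signal, dtype=float)
    expression = np.asarray(expression, dtype=float)
    if peak_signal.shape[1] != expression.shape[1] or peak_signal.shape[1] < 3:
        raise ValueError("need >= 3 shared cell types in both matrices")
    ps = peak_signal - peak_signal.mean(axis=1, keepdims=True)
    ex = expression - expression.mean(axis=1, keepdims=True)
    ps_sd = np.sqrt((ps**2).sum(axis=1))
    ex_sd = np.sqrt((ex**2).sum(axis=1))
    out = []
    n_skipped = 0
    for gi, (chrom, pos, gene) in enumerate(tss):
        for pi, peak in enumerate(peaks):
            if peak.chrom != chrom or abs(peak.midpoint - pos) > max_distance:
                continue
            if ps_sd[pi] == 0 or ex_sd[gi] == 0:
                n_skipped += 1
                continue
            r = float((ps[pi] * ex[gi]).sum() / (ps_sd[pi] * ex_sd[gi]))
            if r >= r_threshold:
                out.append(
                    Link(
                        peak,
                        GenomicInterval(chrom, pos, pos + 1),
                        link_type=LinkType.DNase_TSS,
                        score=r,
                        target_id=gene,
                    )
                )
    if n_skipped:
        logger.warning("predict_activity_links: skipped %d zero-variance pairs", n_skipped)
    return out
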