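"""Core genomic domain types.

All coordinates are 0-based, half-open ``[start, end)``.  File formats that
use 1-based coordinates (genetic map text, some pair tables) are converted at
the I/O boundary, never inside the analysis code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "GenomeAssembly",
    "GenomicInterval",
    "LinkType",
    "Link",
    "DistanceClass",
    "distance_class",
    "DISTANCE_CLASS_BOUNDS",
]


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosome names and lengths (bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in assembly")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_dict(cls, sizes: dict[str, int] | Iterable[tuple[str, int]]) -> "GenomeAssembly":
        items = sizes.items() if isinstance(sizes, dict) else sizes
        return cls(tuple((str(n), int(l)) for n, l in items))

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"chromosome {chrom!r} not in assembly")

    def chrom_index(self, chrom: str) -> int:
        for i, (name, _) in enumerate(self.chromosomes):
            if name == chrom:
                return i
        raise KeyError(f"chromosome {chrom!r} not in assembly")

    def __contains__(self, chrom: str) -> bool:
        return any(name == chrom for name, _ in self.chromosomes)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlap(self, other: "GenomicInterval") -> int:
        """Length of the intersection with *other* (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap between two disjoint intervals; 0 when they touch or overlap."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


class LinkType(str, Enum):
    eQTL = "eQTL"
    meQTL = "meQTL"
    HiC = "HiC"
    ChIAPET = "ChIAPET"
    DNase_TSS = "DNase_TSS"
    enhancer_TSS = "enhancer_TSS"
    other = "other"


# Distance-class boundaries (bp): short 1-10 kb, medium 10-100 kb,
# long 100 kb-1 Mb (right-closed for the long class).
DISTANCE_CLASS_BOUNDS = {
    "SHORT": (1_000, 10_000),
    "MEDIUM": (10_000, 100_000),
    "LONG": (100_000, 1_000_000),
}


class DistanceClass(str, Enum):
    SHORT = "SHORT"
    MEDIUM = "MEDIUM"
    LONG = "LONG"
    EXCLUDED = "EXCLUDED"


def distance_class(distance: float) -> DistanceClass:
    """Classify an anchor-to-anchor distance into the three analysis ranges.

    Classes are half-open on the left boundary set ([1 kb, 10 kb),
    [10 kb, 100 kb), [100 kb, 1 Mb]); anything below 1 kb or above 1 Mb is
    EXCLUDED from the stratified analyses.
    """
    if 1_000 <= distance < 10_000:
        return DistanceClass.SHORT
    if 10_000 <= distance < 100_000:
        return DistanceClass.MEDIUM
    if 100_000 <= distance <= 1_000_000:
        return DistanceClass.LONG
    return DistanceClass.EXCLUDED


@dataclass(frozen=True)
class Link:
    """A two-anchor regulatory link (eQTL/meQTL, Hi-C pair, activity link...).

    Both anchors must lie on the same chromosome.  The *span* is the closed
    hull of the two anchors; the *distance* is measured between anchor
    midpoints (a symmetric convention — the reference point inside each
    anchor is not otherwise constrained).
    """

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    link_type: LinkType = LinkType.other
    score: float = float("nan")
    target_id: str | None = None

    def __post_init__(self) -> None:
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValueError(
                f"link anchors on different chromosomes: "
                f"{self.anchor_a.chrom} vs {self.anchor_b.chrom}"
            )

    @property
    def chrom(self) -> str:
        return self.anchor_a.chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(self.anchor_a.start, self.anchor_b.start),
            max(self.anchor_a.end, self.anchor_b.end),
        )

    @property
    def distance(self) -> float:
        return abs(self.anchor_b.midpoint - self.anchor_a.midpoint)

    @property
    def distance_class(self) -> DistanceClass:
        return distance_class(self.distance)
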