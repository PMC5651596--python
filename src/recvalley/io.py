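"""Readers and writers for the plain-text formats the pipeline touches.

Internal coordinates are 0-based half-open.  Genetic-map text is 1-based by
common convention (switchable); BED/bedGraph/BEDPE are 0-based half-open on
disk and pass through unchanged.  All readers transparently accept gzip
(``.gz``) files.
"""

from __future__ import annotations

import gzip
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomeAssembly, GenomicInterval, Link, LinkType
from .recomb import GeneticMap
from .tracks import FeatureTrack, MethylationTrack

logger = logging.getLogger(__name__)

__all__ = [
    "read_genetic_map",
    "write_genetic_map",
    "read_links",
    "write_links",
    "read_intervals",
    "write_intervals",
    "read_track",
    "write_track",
    "read_methylation",
    "write_methylation",
    "read_assembly",
    "write_assembly",
]


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _data_rows(path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based row number, fields) skipping blank/comment lines."""
    with _open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield i, line.split("\t") if "\t" in line else line.split()


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------- genetic map

MAP_DIALECTS = ("pos_rate_cm", "pos_cm", "pos_rate")


def read_genetic_map(
    path,
    dialect: str = "pos_rate_cm",
    chrom: str | None = None,
    one_based: bool = True,
) -> GeneticMap:
    """Read a genetic map.

    Dialects: ``pos_rate_cm`` (HapMap-style: position, rate cM/Mb, cumulative
    cM), ``pos_cm`` (position, cumulative cM), ``pos_rate`` (position, rate
    over the following inter-marker stretch; cumulative cM reconstructed by
    integration).  A leading chromosome column is auto-detected; without one
    every row is assigned to *chrom*.
    """
    if dialect not in MAP_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {MAP_DIALECTS}")
    per_chrom: dict[str, list[tuple[int, float]]] = {}
    header_skipped = False
    for row_no, fields in _data_rows(path):
        if _is_number(fields[0]):
            c = chrom or "chr1"
            vals = fields
        else:
            expected = 3 if dialect == "pos_rate_cm" else 2
            if len(fields) == expected and not header_skipped:
                header_skipped = True
                continue  # header line like "Position(bp) Rate(cM/Mb) Map(cM)"
            c = fields[0]
            vals = fields[1:]
        try:
            pos = int(float(vals[0]))
            second = float(vals[1])
            third = float(vals[2]) if dialect == "pos_rate_cm" else None
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed map row {row_no}: {fields}") from exc
        if one_based:
            pos -= 1
        if dialect == "pos_rate_cm":
            if second < 0:
                raise ValueError(f"{path}: negative rate at row {row_no}")
            per_chrom.setdefault(c, []).append((pos, third))
        elif dialect == "pos_cm":
            per_chrom.setdefault(c, []).append((pos, second))
        else:  # pos_rate
            if second < 0:
                raise ValueError(f"{path}: negative rate at row {row_no}")
            per_chrom.setdefault(c, []).append((pos, second))

    positions, cum_cm = {}, {}
    for c, rows in per_chrom.items():
        pos = np.array([p for p, _ in rows], dtype=np.int64)
        val = np.array([v for _, v in rows], dtype=float)
        bad = np.nonzero(np.diff(pos) <= 0)[0]
        if bad.size:
            raise ValueError(
                f"{path}: positions not strictly increasing on {c} at data row {bad[0] + 2}"
            )
        if dialect == "pos_rate":
            # integrate piecewise-constant rate: rate[i] applies on [pos_i, pos_{i+1})
            cm = np.concatenate(([0.0], np.cumsum(val[:-1] * np.diff(pos) / 1e6)))
        else:
            cm = val
            bad = np.nonzero(np.diff(cm) < 0)[0]
            if bad.size:
                raise ValueError(
                    f"{path}: cumulative cM decreases on {c} at data row {bad[0] + 2}"
                )
        positions[c] = pos
        cum_cm[c] = cm
    return GeneticMap(positions, cum_cm)


def write_genetic_map(gmap: GeneticMap, path, one_based: bool = True) -> None:
    """Write a map in 3-column HapMap style with a leading chromosome column."""
    off = 1 if one_based else 0
    with _open(path, "wt") as fh:
        for chrom in gmap.chromosomes:
            pos = gmap.positions[chrom]
            cm = gmap.cum_cm[chrom]
            rates = np.concatenate((gmap.marker_rates(chrom), [0.0]))
            for p, r, c in zip(pos, rates, cm):
                fh.write(f"{chrom}\t{p + off}\t{r:.8g}\t{c:.10g}\n")


# ---------------------------------------------------------------------- links

LINK_FORMATS = ("bedpe", "pairs")


def read_links(path, format: str = "bedpe", link_type: LinkType = LinkType.other) -> list[Link]:
    """Read a link set.

    ``bedpe``: chrom1 start1 end1 chrom2 start2 end2 [name score].
    ``pairs``: chrom posA posB score [target] with 1-bp anchors (0-based
    positions).  Inter-chromosomal rows are counted, logged, and dropped.
    """
    if format not in LINK_FORMATS:
        raise ValueError(f"unknown link format {format!r}; choose from {LINK_FORMATS}")
    links: list[Link] = []
    n_trans = 0
    for row_no, f in _data_rows(path):
        try:
            if format == "bedpe":
                c1, s1, e1, c2, s2, e2 = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
                name = f[6] if len(f) > 6 else None
                score = float(f[7]) if len(f) > 7 else float("nan")
                if c1 != c2:
                    n_trans += 1
                    continue
                links.append(
                    Link(
                        GenomicInterval(c1, s1, e1),
                        GenomicInterval(c2, s2, e2),
                        link_type=link_type,
                        score=score,
                        target_id=None if name in (None, ".") else name,
                    )
                )
            else:
                c, pa, pb = f[0], int(f[1]), int(f[2])
                score = float(f[3]) if len(f) > 3 else float("nan")
                target = f[4] if len(f) > 4 else None
                links.append(
                    Link(
                        GenomicInterval(c, pa, pa + 1),
                        GenomicInterval(c, pb, pb + 1),
                        link_type=link_type,
                        score=score,
                        target_id=target,
                    )
                )
        except (ValueError, IndexError) as exc:
            if isinstance(exc, ValueError) and "invalid interval" in str(exc):
                raise ValueError(f"{path}: bad coordinates at row {row_no}") from exc
            raise ValueError(f"{path}: malformed link row {row_no}: {f}") from exc
    if n_trans:
        logger.info("dropped %d inter-chromosomal link rows from %s", n_trans, path)
    return links


def write_links(links: Sequence[Link], path) -> None:
    """Write links as BEDPE (name column carries the target id)."""
    with _open(path, "wt") as fh:
        for ln in links:
            a, b = ln.anchor_a, ln.anchor_b
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t"
                f"{ln.target_id or '.'}\t{ln.score:.8g}\t{ln.link_type.value}\n"
            )


# ------------------------------------------------------------------ intervals

def read_intervals(path, assembly: GenomeAssembly | None = None) -> list[GenomicInterval]:
    """Read BED intervals; intervals beyond the chromosome end are clipped."""
    out = []
    for row_no, f in _data_rows(path):
        try:
            chrom, start, end = f[0], int(f[1]), int(f[2])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed BED row {row_no}: {f}") from exc
        if assembly is not None:
            if chrom not in assembly:
                raise ValueError(f"{path}: unknown chromosome {chrom!r} at row {row_no}")
            L = assembly.length(chrom)
            if end > L:
                logger.warning("%s row %d: interval end %d clipped to %d", path, row_no, end, L)
                end = L
        out.append(GenomicInterval(chrom, start, end))
    return out


def write_intervals(intervals: Sequence[GenomicInterval], path) -> None:
    with _open(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# --------------------------------------------------------------------- tracks

def read_track(
    path,
    assembly: GenomeAssembly,
    bin_size: int = 1_000,
    feature_name: str | None = None,
    uncovered: str = "zero",
) -> FeatureTrack:
    """Read a bedGraph into fixed-size bins, averaging values by base overlap.

    ``uncovered="zero"`` (default) counts bases without a record as value 0,
    the natural convention for density tracks; ``uncovered="missing"``
    averages over covered bases only (a fully uncovered bin gets 0).
    """
    if uncovered not in ("zero", "missing"):
        raise ValueError("uncovered must be 'zero' or 'missing'")
    sums: dict[str, np.ndarray] = {}
    cov: dict[str, np.ndarray] = {}
    nbins = {
        chrom: int(np.ceil(length / bin_size)) for chrom, length in assembly.chromosomes
    }
    for row_no, f in _data_rows(path):
        try:
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed bedGraph row {row_no}: {f}") from exc
        if chrom not in nbins:
            raise ValueError(f"{path}: unknown chromosome {chrom!r} at row {row_no}")
        L = assembly.length(chrom)
        if end > L:
            logger.warning("%s row %d: record end %d clipped to %d", path, row_no, end, L)
            end = min(end, L)
        if chrom not in sums:
            sums[chrom] = np.zeros(nbins[chrom])
            cov[chrom] = np.zeros(nbins[chrom])
        b0, b1 = start // bin_size, (end - 1) // bin_size
        for b in range(b0, b1 + 1):
            lo = max(start, b * bin_size)
            hi = min(end, (b + 1) * bin_size, L)
            if hi > lo:
                sums[chrom][b] += value * (hi - lo)
                cov[chrom][b] += hi - lo
    values = {}
    for chrom, n in nbins.items():
        s = sums.get(chrom, np.zeros(n))
        c = cov.get(chrom, np.zeros(n))
        L = assembly.length(chrom)
        widths = np.minimum((np.arange(n) + 1) * bin_size, L) - np.arange(n) * bin_size
        if uncovered == "zero":
            values[chrom] = s / widths
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                v = np.where(c > 0, s / np.maximum(c, 1), 0.0)
            values[chrom] = v
    return FeatureTrack(feature_name or Path(path).stem, bin_size, values)


def write_track(track: FeatureTrack, path) -> None:
    """Write a binned track as bedGraph (one record per bin)."""
    with _open(path, "wt") as fh:
        for chrom, vals in track.values.items():
            for i, v in enumerate(vals):
                fh.write(
                    f"{chrom}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{v:.8g}\n"
                )


# ---------------------------------------------------------------- methylation

def read_methylation(path) -> MethylationTrack:
    """Read a CpG-resolution bedGraph (chrom, pos, pos+1, level in [0, 1])."""
    pos: dict[str, list[int]] = {}
    lev: dict[str, list[float]] = {}
    for row_no, f in _data_rows(path):
        try:
            chrom, p, value = f[0], int(f[1]), float(f[3] if len(f) > 3 else f[2])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed methylation row {row_no}: {f}") from exc
        pos.setdefault(chrom, []).append(p)
        lev.setdefault(chrom, []).append(value)
    return MethylationTrack(
        {c: np.array(v, dtype=np.int64) for c, v in pos.items()},
        {c: np.array(v, dtype=float) for c, v in lev.items()},
    )


def write_methylation(track: MethylationTrack, path) -> None:
    with _open(path, "wt") as fh:
        for chrom in track.positions:
            for p, v in zip(track.positions[chrom], track.levels[chrom]):
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{v:.6g}\n")


# ------------------------------------------------------------------- assembly

def read_assembly(path) -> GenomeAssembly:
    """Read a chrom.sizes file (chrom<TAB>length)."""
    items = []
    for row_no, f in _data_rows(path):
        try:
            items.append((f[0], int(f[1])))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed chrom.sizes row {row_no}") from exc
    return GenomeAssembly(tuple(items))


def write_assembly(assembly: GenomeAssembly, path) -> None:
    with _open(path, "wt") as fh:
        for chrom, length in assembly.chromosomes:
            fh.write(f"{chrom}\t{length}\n")
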