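"""Binned feature tracks and CpG-resolution methylation tracks.

A :class:`FeatureTrack` stores one value per fixed-size bin per chromosome
(GC fraction, CpG density, SNP density, PRDM9 motif density, ...).  Interval
queries integrate the piecewise-constant bin signal exactly, weighting
partial bins by overlap.  Each track carries its own (min, max) normalisation
constants so that control matching can work in a common [0, 1] feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeAssembly

__all__ = ["FeatureTrack", "MethylationTrack"]


@dataclass
class FeatureTrack:
    feature_name: str
    bin_size: int
    values: dict[str, np.ndarray]
    normalization: tuple[float, float] | None = None
    _cum: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite track values on {chrom}")
            self.values[chrom] = arr
        if self.normalization is None:
            lo = min((float(a.min()) for a in self.values.values() if a.size), default=0.0)
            hi = max((float(a.max()) for a in self.values.values() if a.size), default=1.0)
            if hi <= lo:
                hi = lo + 1.0
            self.normalization = (lo, hi)

    def _cumsum(self, chrom: str) -> np.ndarray:
        # integral of the bin signal from the chromosome start to each bin edge
        if chrom not in self._cum:
            v = self.values[chrom]
            self._cum[chrom] = np.concatenate(([0.0], np.cumsum(v))) * self.bin_size
        return self._cum[chrom]

    def _integral(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of the piecewise-constant signal over [0, pos)."""
        v = self.values[chrom]
        cum = self._cumsum(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        b = np.minimum(pos // self.bin_size, len(v) - 1)
        frac = pos - b * self.bin_size
        return cum[b] + v[b] * frac

    def interval_mean(self, chrom: str, start, end) -> np.ndarray | float:
        """Overlap-weighted mean of bin values over ``[start, end)``.

        Accepts scalars or equal-length arrays of starts/ends.
        """
        scalar = np.isscalar(start)
        start = np.atleast_1d(np.asarray(start, dtype=np.int64))
        end = np.atleast_1d(np.asarray(end, dtype=np.int64))
        out = (self._integral(chrom, end) - self._integral(chrom, start)) / (end - start)
        return float(out[0]) if scalar else out

    def normalized_interval_mean(self, chrom: str, start, end) -> np.ndarray | float:
        lo, hi = self.normalization
        return (self.interval_mean(chrom, start, end) - lo) / (hi - lo)

    def window_means(self, assembly: GenomeAssembly, window: int) -> dict[str, np.ndarray]:
        """Per-window means over non-overlapping windows of *window* bp."""
        out = {}
        for chrom, length in assembly.chromosomes:
            if chrom not in self.values:
                continue
            n = int(np.ceil(length / window))
            starts = np.arange(n, dtype=np.int64) * window
            ends = np.minimum(starts + window, length)
            out[chrom] = np.asarray(self.interval_mean(chrom, starts, ends))
        return out


@dataclass
class MethylationTrack:
    """Per-CpG methylation levels (strictly increasing positions, levels in [0, 1])."""

    positions: dict[str, np.ndarray]
    levels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom in self.positions:
            pos = np.asarray(self.positions[chrom], dtype=np.int64)
            lev = np.asarray(self.levels[chrom], dtype=float)
            if pos.shape != lev.shape:
                raise ValueError(f"positions/levels length mismatch on {chrom}")
            if pos.size > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"CpG positions not strictly increasing on {chrom}")
            if lev.size and (lev.min() < 0 or lev.max() > 1):
                raise ValueError(f"methylation levels outside [0, 1] on {chrom}")
            self.positions[chrom] = pos
            self.levels[chrom] = lev

    def interval_mean(self, chrom: str, start: int, end: int) -> float:
        """Unweighted mean CpG level over [start, end); NaN when no CpG inside."""
        if chrom not in self.positions:
            return float("nan")
        pos = self.positions[chrom]
        i, j = np.searchsorted(pos, [start, end])
        if j <= i:
            return float("nan")
        return float(self.levels[chrom][i:j].mean())

    def interval_means(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        pos = self.positions.get(chrom, np.empty(0, dtype=np.int64))
        lev = self.levels.get(chrom, np.empty(0))
        csum = np.concatenate(([0.0], np.cumsum(lev)))
        i = np.searchsorted(pos, starts)
        j = np.searchsorted(pos, ends)
        n = (j - i).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (csum[j] - csum[i]) / n
        out[n == 0] = np.nan
        return out

    def window_means(self, assembly: GenomeAssembly, window: int) -> dict[str, np.ndarray]:
        out = {}
        for chrom, length in assembly.chromosomes:
            if chrom not in self.positions:
                continue
            n = int(np.ceil(length / window))
            starts = np.arange(n, dtype=np.int64) * window
            ends = np.minimum(starts + window, length)
            out[chrom] = self.interval_means(chrom, starts, ends)
        return out
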