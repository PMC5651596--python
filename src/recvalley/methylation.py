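"""Methylation-recombination correlation analyses and the rate predictor.

Covers the genome-scan correlation between a methylation track and the
recombination landscape (500-kb non-overlapping windows by default), the
per-link methylation-quantile rate profile, the interval feature table
(chromosome, length, per-link-type overlap fraction, mean methylation), a
random-forest recombination-rate predictor with chromosome-stratified
cross-validation, and the depletion-recapitulation fraction — how much of
the observed link-vs-control rate difference the predictor reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor

from .genome import GenomeAssembly, GenomicInterval, Link
from .recomb import GeneticMap, link_rates
from .tracks import FeatureTrack, MethylationTrack

__all__ = [
    "window_correlation",
    "quantile_rate_profile",
    "interval_feature_table",
    "RatePredictor",
    "RatePredictorResults",
    "train_rate_predictor",
    "depletion_recapitulation",
]

MISSING_METH = -1.0  # flag value for intervals without a CpG


def window_correlation(
    track_x,
    track_y,
    assembly: GenomeAssembly,
    window: int = 500_000,
    method: str = "pearson",
) -> tuple[float, float, int]:
    """Correlation of two tracks across non-overlapping genome windows.

    Both arguments must expose ``window_means(assembly, window)`` (feature
    tracks, methylation tracks, or a rate track projected from a genetic
    map).  Windows missing data in either track are dropped; at least three
    informative windows are required.
    """
    if window < 1:
        raise ValueError("window must be >= 1 bp")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    wx = track_x.window_means(assembly, window)
    wy = track_y.window_means(assembly, window)
    xs, ys = [], []
    for chrom in wx:
        if chrom not in wy:
            continue
        n = min(len(wx[chrom]), len(wy[chrom]))
        xs.append(wx[chrom][:n])
        ys.append(wy[chrom][:n])
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"only {x.size} informative windows; need >= 3")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        r, p = sps.spearmanr(x, y)
    return float(r), float(p), int(x.size)


def quantile_rate_profile(
    links: Sequence[Link],
    methylation: MethylationTrack,
    gmap: GeneticMap,
    n_quantiles: int = 10,
) -> pd.DataFrame:
    """Mean rate per methylation quantile of the link spans.

    Each link's methylation is the unweighted mean CpG level over its span
    (links without a CpG are dropped).  Ties on a quantile edge go to the
    lowest applicable quantile.  Error bars are the per-bin standard
    deviation (ddof=1, 0 for singleton bins).
    """
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    meth = np.array(
        [methylation.interval_mean(ln.chrom, ln.span.start, ln.span.end) for ln in links]
    )
    keep = np.isfinite(meth)
    kept = [ln for ln, k in zip(links, keep) if k]
    meth = meth[keep]
    if len(kept) < n_quantiles:
        raise ValueError(f"{len(kept)} links with CpG coverage < {n_quantiles} quantiles")
    rates = link_rates(kept, gmap)
    edges = np.quantile(meth, np.arange(1, n_quantiles) / n_quantiles)
    bins = np.searchsorted(edges, meth, side="left")
    rows = []
    for q in range(n_quantiles):
        sel = bins == q
        n = int(sel.sum())
        rows.append(
            {
                "quantile": q,
                "n": n,
                "meth_mean": float(meth[sel].mean()) if n else np.nan,
                "mean_rate": float(rates[sel].mean()) if n else np.nan,
                "sd_rate": float(rates[sel].std(ddof=1)) if n > 1 else (0.0 if n else np.nan),
            }
        )
    return pd.DataFrame(rows)


def _merged_spans(links: Sequence[Link]) -> dict[str, np.ndarray]:
    per: dict[str, list[tuple[int, int]]] = {}
    for ln in links:
        sp = ln.span
        per.setdefault(sp.chrom, []).append((sp.start, sp.end))
    out = {}
    for chrom, ivs in per.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged, dtype=np.int64)
    return out


def _coverage_fraction(merged: dict[str, np.ndarray], iv: GenomicInterval) -> float:
    arr = merged.get(iv.chrom)
    if arr is None:
        return 0.0
    cov = 0
    lo = np.searchsorted(arr[:, 1], iv.start, side="right")
    for s, e in arr[lo:]:
        if s >= iv.end:
            break
        cov += min(e, iv.end) - max(s, iv.start)
    return cov / iv.length


def interval_feature_table(
    intervals: Sequence[GenomicInterval],
    linksets_by_type: dict[str, Sequence[Link]],
    methylation: MethylationTrack | None,
    assembly: GenomeAssembly,
) -> pd.DataFrame:
    """Feature matrix for the rate predictor: one row per interval.

    Columns: chromosome index (categorical adjustment variable), interval
    length, per-link-type fraction of the interval covered by the merged
    link spans, and mean methylation (flagged ``-1`` when no CpG falls in
    the interval).
    """
    merged = {name: _merged_spans(links) for name, links in linksets_by_type.items()}
    rows = []
    for iv in intervals:
        row = {
            "chrom": assembly.chrom_index(iv.chrom),
            "length": iv.length,
        }
        for name in linksets_by_type:
            row[f"overlap_{name}"] = _coverage_fraction(merged[name], iv)
        if methylation is not None:
            m = methylation.interval_mean(iv.chrom, iv.start, iv.end)
            row["methylation"] = m if np.isfinite(m) else MISSING_METH
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RatePredictorResults:
    """Fitted predictor with pooled out-of-fold evaluation."""

    model: RandomForestRegressor
    cv_pearson: float  # NaN when the target (or predictions) are constant
    cv_mse: float
    oof_predictions: np.ndarray
    feature_names: list[str]
    n_folds: int
    seed: int | None

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.model.predict(features[self.feature_names].to_numpy())

    def summary(self) -> str:
        return (
            "Random-forest recombination-rate predictor\n"
            f"  features: {', '.join(self.feature_names)}\n"
            f"  {self.n_folds}-fold chromosome-stratified CV "
            f"(n={len(self.oof_predictions)})\n"
            f"  out-of-fold Pearson r: {self.cv_pearson:.4f}\n"
            f"  out-of-fold MSE: {self.cv_mse:.6g}"
        )


class RatePredictor:
    """Random-forest regression of interval recombination rate on features.

    The default forest (500 trees, unlimited depth) is evaluated by pooled
    out-of-fold predictions under chromosome-stratified K-fold CV, then
    refitted on the full data.
    """

    def __init__(self, features: pd.DataFrame, rates: Sequence[float]) -> None:
        if len(features) != len(rates):
            raise ValueError("features and rates must have equal length")
        if len(features) < 50:
            raise ValueError("need >= 50 intervals to train the predictor")
        self.features = features.reset_index(drop=True)
        self.rates = np.asarray(rates, dtype=float)

    def fit(
        self,
        cv_folds: int = 5,
        n_trees: int = 500,
        seed: int | None = 0,
    ) -> RatePredictorResults:
        if cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        rng = np.random.default_rng(seed)
        n = len(self.rates)
        folds = np.empty(n, dtype=int)
        chroms = (
            self.features["chrom"].to_numpy()
            if "chrom" in self.features
            else np.zeros(n, dtype=int)
        )
        # stratify fold assignment within each chromosome
        for c in np.unique(chroms):
            idx = np.nonzero(chroms == c)[0]
            idx = rng.permutation(idx)
            folds[idx] = np.arange(len(idx)) % cv_folds
        X = self.features.to_numpy(dtype=float)
        rf_seed = None if seed is None else int(seed) % (2**31)
        oof = np.empty(n)
        for f in range(cv_folds):
            test = folds == f
            model = RandomForestRegressor(
                n_estimators=n_trees, random_state=rf_seed, n_jobs=1
            )
            model.fit(X[~test], self.rates[~test])
            oof[test] = model.predict(X[test])
        mse = float(np.mean((oof - self.rates) ** 2))
        if np.std(self.rates) == 0 or np.std(oof) == 0:
            r = float("nan")
        else:
            r = float(sps.pearsonr(oof, self.rates)[0])
        final = RandomForestRegressor(n_estimators=n_trees, random_state=rf_seed, n_jobs=1)
        final.fit(X, self.rates)
        return RatePredictorResults(
            model=final,
            cv_pearson=r,
            cv_mse=mse,
            oof_predictions=oof,
            feature_names=list(self.features.columns),
            n_folds=cv_folds,
            seed=seed,
        )


def train_rate_predictor(
    features: pd.DataFrame,
    rates: Sequence[float],
    cv_folds: int = 5,
    seed: int | None = 0,
) -> tuple[RatePredictorResults, float, float]:
    """Functional wrapper: returns (results, cv_pearson, cv_mse)."""
    res = RatePredictor(features, rates).fit(cv_folds=cv_folds, seed=seed)
    return res, res.cv_pearson, res.cv_mse


def depletion_recapitulation(
    predicted_link_rates: Sequence[float],
    predicted_control_rates: Sequence[float],
    observed_link_rates: Sequence[float],
    observed_control_rates: Sequence[float],
) -> tuple[float, float]:
    """Fraction of the observed link-vs-control rate difference recapitulated.

    ``(mean predicted control - mean predicted link) /
    (mean observed control - mean observed link)``.  Returns the raw value
    and a [0, 1]-clipped companion; NaN when the observed difference is 0.
    """
    obs_diff = float(np.mean(observed_control_rates) - np.mean(observed_link_rates))
    if obs_diff == 0:
        return float("nan"), float("nan")
    pred_diff = float(np.mean(predicted_control_rates) - np.mean(predicted_link_rates))
    raw = pred_diff / obs_diff
    return raw, float(np.clip(raw, 0.0, 1.0))
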