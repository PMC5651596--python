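"""The recombination-rate valley test, statsmodels-style.

:class:`RecombinationValleyModel` is built from a link set, a genetic map
and a genome assembly; :meth:`~RecombinationValleyModel.fit` generates
matched controls under a chosen strategy, runs the paired rank test per
distance class (and the median-permutation test against the null pair
universe when point sets are supplied), and returns a
:class:`ValleyTestResults` carrying the per-class estimates, p-values and a
``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import controls as ctrl
from .controls import ControlPair, ControlSet
from .genome import DistanceClass, GenomeAssembly, GenomicInterval, Link
from .recomb import GeneticMap, link_rates, interval_rates
from .stats import (
    PairedRankResult,
    PermutationResult,
    paired_rank_test,
    permutation_median_test,
)
from .tracks import FeatureTrack

__all__ = [
    "RecombinationValleyModel",
    "ValleyTestResults",
    "ClassResult",
    "GroupCompareResult",
    "group_compare",
    "CONTROL_STRATEGIES",
]

CONTROL_STRATEGIES = ("length", "rejection", "kdtree", "domain", "self")


@dataclass
class ClassResult:
    """Per-distance-class outcome of the valley test."""

    distance_class: str
    n_links: int
    mean_observed: float
    median_observed: float
    mean_control: float
    median_control: float
    paired_statistic: float
    paired_p: float
    paired_n_effective: int
    paired_method: str
    perm_p: float | None
    perm_observed_median: float | None
    null_median_mean: float | None
    null_median_sd: float | None
    significant: bool


@dataclass
class ValleyTestResults:
    """Results container with serialization and a printable summary."""

    classes: dict[str, ClassResult]
    alpha: float
    control_strategy: str
    n_perm: int | None
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(c) for c in self.classes.values()]).set_index(
            "distance_class"
        )

    def summary(self) -> str:
        df = self.to_frame()
        cols = [
            "n_links",
            "mean_observed",
            "mean_control",
            "median_observed",
            "median_control",
            "paired_p",
            "perm_p",
            "significant",
        ]
        lines = [
            "Recombination rate valley test",
            f"  control strategy: {self.control_strategy}"
            f"   alpha: {self.alpha:g}   n_perm: {self.n_perm}",
            "  paired test: two-sided Wilcoxon signed-rank (zero differences dropped)",
            "  permutation test: one-sided depletion, +1 corrected",
            "",
            df[cols].to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "classes": {k: asdict(v) for k, v in self.classes.items()},
            "alpha": self.alpha,
            "control_strategy": self.control_strategy,
            "n_perm": self.n_perm,
            "metadata": self.metadata,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ValleyTestResults":
        return cls(
            classes={k: ClassResult(**v) for k, v in d["classes"].items()},
            alpha=d["alpha"],
            control_strategy=d["control_strategy"],
            n_perm=d["n_perm"],
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def from_json(cls, path) -> "ValleyTestResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def make_controls(
    links: Sequence[Link],
    strategy: str,
    assembly: GenomeAssembly,
    rng: np.random.Generator,
    tracks: Sequence[FeatureTrack] | None = None,
    domains: Sequence[GenomicInterval] | None = None,
    candidate_index: ctrl.CandidateIndex | None = None,
    ctcf_motifs: Sequence[GenomicInterval] | None = None,
    tolerance: float = 0.01,
    max_iter: int = 10_000,
    k: int = 1_000,
) -> ControlSet:
    """Generate one matched control per link under the chosen strategy.

    Strategies: ``length`` (same chromosome + exact length), ``rejection``
    (feature-matched rejection sampling), ``kdtree`` (nearest-neighbour in
    the candidate index), ``domain`` (same length inside the containing
    domain; uncontained links skipped), ``self`` (control = the span itself;
    degenerate comparator for testing).
    """
    if strategy not in CONTROL_STRATEGIES:
        raise ValueError(f"unknown control strategy {strategy!r}; choose from {CONTROL_STRATEGIES}")
    pairs: list[ControlPair] = []
    if strategy == "kdtree" and candidate_index is None:
        if tracks is None:
            raise ValueError("kdtree strategy requires tracks or a prebuilt candidate_index")
        candidate_index = ctrl.build_candidate_index(assembly, tracks)
    for ln in links:
        if strategy == "length":
            iv = ctrl.sample_length_matched(ln, assembly, rng)
            pairs.append(ControlPair(ln, iv, float("nan"), 1, True))
        elif strategy == "rejection":
            pairs.append(
                ctrl.sample_feature_matched_rejection(
                    ln, tracks or [], assembly, rng, tolerance=tolerance, max_iter=max_iter
                )
            )
        elif strategy == "kdtree":
            iv = ctrl.sample_kdtree_matched(
                candidate_index, ln, rng, k=k, ctcf_motifs=ctcf_motifs
            )
            # k-d controls may land on another chromosome/length (both are
            # matching features, not hard constraints) -> not a ControlSet pair
            pairs.append(ControlPair(ln, iv, float("nan"), 1, True))
        elif strategy == "domain":
            iv = ctrl.sample_within_domain(ln, domains or [], rng)
            if iv is not None:
                pairs.append(ControlPair(ln, iv, float("nan"), 1, True))
        else:  # self
            pairs.append(ControlPair(ln, ln.span, 0.0, 0, True))
    if strategy == "kdtree":
        cs = ControlSet.__new__(ControlSet)  # skip same-length/chrom validation
        cs.pairs = pairs
        return cs
    return ControlSet(pairs)


class RecombinationValleyModel:
    """Test for reduced recombination rate within regulatory-domain links.

    Parameters
    ----------
    links : link set under test (anchors on one chromosome each).
    gmap : genetic map (the rate oracle).
    assembly : chromosome names and lengths.
    tracks : feature tracks for feature-matched control strategies.
    ctcf_motifs, domains : optional interval sets for the k-d tree CTCF
        exclusion and the domain-constrained strategy.
    snp_positions, tss_positions : per-chromosome point sets defining the
        null pair universe for the permutation test; when omitted only the
        paired rank test is run.
    """

    def __init__(
        self,
        links: Sequence[Link],
        gmap: GeneticMap,
        assembly: GenomeAssembly,
        tracks: Sequence[FeatureTrack] | None = None,
        ctcf_motifs: Sequence[GenomicInterval] | None = None,
        domains: Sequence[GenomicInterval] | None = None,
        snp_positions: dict[str, np.ndarray] | None = None,
        tss_positions: dict[str, np.ndarray] | None = None,
    ) -> None:
        if not links:
            raise ValueError("links must be non-empty")
        self.links = list(links)
        self.gmap = gmap
        self.assembly = assembly
        self.tracks = list(tracks) if tracks else []
        self.ctcf_motifs = list(ctcf_motifs) if ctcf_motifs else None
        self.domains = list(domains) if domains else None
        self.snp_positions = snp_positions
        self.tss_positions = tss_positions

    def fit(
        self,
        control_strategy: str = "length",
        n_perm: int = 10_000,
        alpha: float = 1e-4,
        tolerance: float = 0.01,
        max_iter: int = 10_000,
        k: int = 1_000,
        include_unmatched: bool = False,
        candidate_index: ctrl.CandidateIndex | None = None,
        seed: int | np.random.Generator | None = None,
    ) -> ValleyTestResults:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        by_class: dict[DistanceClass, list[Link]] = {}
        for ln in self.links:
            if ln.distance_class != DistanceClass.EXCLUDED:
                by_class.setdefault(ln.distance_class, []).append(ln)

        perm: dict[DistanceClass, PermutationResult] = {}
        if self.snp_positions is not None and self.tss_positions is not None:
            perm = permutation_median_test(
                [ln for lst in by_class.values() for ln in lst],
                self.gmap,
                self.snp_positions,
                self.tss_positions,
                n_perm=n_perm,
                rng=rng,
            )

        classes: dict[str, ClassResult] = {}
        for cls in (DistanceClass.SHORT, DistanceClass.MEDIUM, DistanceClass.LONG):
            cls_links = by_class.get(cls)
            if not cls_links:
                continue
            cset = make_controls(
                cls_links,
                control_strategy,
                self.assembly,
                rng,
                tracks=self.tracks,
                domains=self.domains,
                candidate_index=candidate_index,
                ctcf_motifs=self.ctcf_motifs,
                tolerance=tolerance,
                max_iter=max_iter,
                k=k,
            )
            pairs = [
                p for p in cset.pairs if p.matched or include_unmatched
            ]
            obs = link_rates([p.link for p in pairs], self.gmap)
            ctrl_rates = np.empty(len(pairs))
            by_chrom: dict[str, list[int]] = {}
            for i, p in enumerate(pairs):
                by_chrom.setdefault(p.control.chrom, []).append(i)
            for chrom, idx in by_chrom.items():
                s = np.array([pairs[i].control.start for i in idx], dtype=float)
                e = np.array([pairs[i].control.end for i in idx], dtype=float)
                ctrl_rates[idx] = interval_rates(self.gmap, chrom, s, e)
            pr: PairedRankResult = paired_rank_test(obs, ctrl_rates)
            pm = perm.get(cls)
            sig = pr.pvalue <= alpha and (pm is None or pm.pvalue <= alpha)
            classes[cls.value] = ClassResult(
                distance_class=cls.value,
                n_links=len(pairs),
                mean_observed=float(obs.mean()),
                median_observed=float(np.median(obs)),
                mean_control=float(ctrl_rates.mean()),
                median_control=float(np.median(ctrl_rates)),
                paired_statistic=pr.statistic,
                paired_p=pr.pvalue,
                paired_n_effective=pr.n_effective,
                paired_method=pr.method,
                perm_p=pm.pvalue if pm else None,
                perm_observed_median=pm.observed_median if pm else None,
                null_median_mean=pm.null_median_mean if pm else None,
                null_median_sd=pm.null_median_sd if pm else None,
                significant=bool(sig),
            )
        return ValleyTestResults(
            classes=classes,
            alpha=alpha,
            control_strategy=control_strategy,
            n_perm=n_perm if perm else None,
            metadata={
                "paired_test": "wilcoxon_signed_rank_two_sided_zeros_dropped",
                "permutation_test": "one_sided_depletion_plus_one_corrected",
                "n_links_input": len(self.links),
            },
        )


@dataclass(frozen=True)
class GroupCompareResult:
    depletion_a: float
    depletion_b: float
    delta: float
    pvalue: float  # two-sided label-permutation p, +1 corrected
    n_a: int
    n_b: int


def group_compare(
    links_a: Sequence[Link],
    links_b: Sequence[Link],
    gmap: GeneticMap,
    assembly: GenomeAssembly,
    control_strategy: str = "length",
    n_perm_labels: int = 10_000,
    seed: int | np.random.Generator | None = None,
    **control_kwargs,
) -> GroupCompareResult:
    """Compare rate depletion between two link groups by label permutation.

    Depletion per group is mean(control rate) - mean(observed rate) over its
    per-link matched controls; the difference of depletions is tested by
    permuting group labels over the pooled per-link depletion values.
    """
    if not links_a or not links_b:
        raise ValueError("both groups must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def per_link_depletion(links: Sequence[Link]) -> np.ndarray:
        cset = make_controls(links, control_strategy, assembly, rng, **control_kwargs)
        pairs = [p for p in cset.pairs if p.matched]
        obs = link_rates([p.link for p in pairs], gmap)
        c = np.empty(len(pairs))
        by_chrom: dict[str, list[int]] = {}
        for i, p in enumerate(pairs):
            by_chrom.setdefault(p.control.chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            s = np.array([pairs[i].control.start for i in idx], dtype=float)
            e = np.array([pairs[i].control.end for i in idx], dtype=float)
            c[idx] = interval_rates(gmap, chrom, s, e)
        return c - obs

    da = per_link_depletion(links_a)
    db = per_link_depletion(links_b)
    delta = float(da.mean() - db.mean())
    pooled = np.concatenate((da, db))
    na = len(da)
    mat = np.tile(pooled, (n_perm_labels, 1))
    mat = rng.permuted(mat, axis=1)
    deltas = mat[:, :na].mean(axis=1) - mat[:, na:].mean(axis=1)
    p = (1 + int((np.abs(deltas) >= abs(delta)).sum())) / (1 + n_perm_labels)
    return GroupCompareResult(
        depletion_a=float(da.mean()),
        depletion_b=float(db.mean()),
        delta=delta,
        pvalue=float(p),
        n_a=na,
        n_b=len(db),
    )
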