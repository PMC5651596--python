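"""Synthetic genomes with planted recombination-rate valleys.

The generator emulates the statistical structure the valley analysis
assumes: a piecewise-constant recombination landscape (baseline rate,
multiplicative hotspots, domain-shaped valleys), link sets whose spans
preferentially fall inside the valley domains, spatially autocorrelated
feature tracks for control matching, a TSS/SNP point universe for the
permutation null, CTCF motifs placed outside domains (so the planted links
are uninterrupted), and a methylation track coupled to the domain-scale
recombination rate at a configurable correlation.

Three named presets: ``planted_valley`` (the study condition: 2 x 20 Mb,
markers every 500 bp, baseline 1 cM/Mb, 40 domains of 100-400 kb at
multiplier 0.5, 400 links with 90% placed inside domains, distances
10-600 kb), ``null`` (identical but multiplier 1 — no planted effect), and
``methylation_coupled`` (planted valleys plus rate-coupled methylation,
rho = -0.8).  A small ``toy`` preset exists for fast smoke tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GenomeAssembly, GenomicInterval, Link, LinkType
from .recomb import GeneticMap, interval_rates
from .tracks import FeatureTrack, MethylationTrack

__all__ = ["ScenarioConfig", "Scenario", "PRESETS", "make_scenario",
           "make_genetic_map", "make_links", "make_tracks", "make_methylation",
           "write_scenario", "load_scenario"]


@dataclass(frozen=True)
class ScenarioConfig:
    n_chromosomes: int = 2
    chrom_length: int = 20_000_000
    snp_spacing: int = 500
    baseline_rate: float = 1.0          # cM/Mb
    hotspot_density_per_mb: float = 10.0
    hotspot_multiplier: float = 10.0
    hotspot_width: int = 2_000
    n_domains: int = 40                 # total across the genome
    domain_length_range: tuple[int, int] = (100_000, 400_000)
    valley_multiplier: float = 0.5      # in (0, 1]; 1 = no planted effect
    n_links: int = 400
    link_distance_range: tuple[int, int] = (10_000, 600_000)
    inside_fraction: float = 0.9
    # "domains": inside_fraction of links inside domains, rest strictly
    # outside; "uniform": place links uniformly, ignoring domains (the null
    # condition — without planted valleys, domain-clustered placement would
    # only introduce pseudo-replication among overlapping spans)
    link_placement: str = "domains"
    link_type: LinkType = LinkType.eQTL
    # feature tracks
    track_bin_size: int = 1_000
    track_smoothness: int = 2           # moving-average window, in bins
    # methylation
    methylation_coupling: float = -0.8  # window-level correlation with rate
    methylation_noise_sd: float = 0.05  # per-CpG noise
    methylation_mean: float = 0.7
    methylation_sd: float = 0.1         # amplitude of the coupled component
    cpg_spacing: int = 200
    coupling_scale: int = 100_000       # rate is smoothed to this scale first
    # point universes / motifs
    n_tss_per_chrom: int = 500
    n_ctcf_per_chrom: int = 400
    ctcf_motif_width: int = 19
    plant_interrupting_ctcf: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.valley_multiplier <= 1):
            raise ValueError("valley_multiplier must be in (0, 1]")
        if not (0 <= self.inside_fraction <= 1):
            raise ValueError("inside_fraction must be in [0, 1]")
        if self.link_placement not in ("domains", "uniform"):
            raise ValueError("link_placement must be 'domains' or 'uniform'")
        if not (-1 <= self.methylation_coupling <= 1):
            raise ValueError("methylation_coupling must be in [-1, 1]")
        for name in ("n_chromosomes", "chrom_length", "snp_spacing", "n_links",
                     "track_bin_size", "track_smoothness", "cpg_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def assembly(self) -> GenomeAssembly:
        return GenomeAssembly(
            tuple((f"chr{i + 1}", self.chrom_length) for i in range(self.n_chromosomes))
        )


PRESETS: dict[str, ScenarioConfig] = {
    "planted_valley": ScenarioConfig(),
    "null": ScenarioConfig(valley_multiplier=1.0, link_placement="uniform"),
    "methylation_coupled": ScenarioConfig(methylation_coupling=-0.8),
    # methylation fully determines the valley landscape: no hotspots, no
    # CpG-level noise, perfect (negative) coupling at a fine spatial scale
    "mechanism": ScenarioConfig(
        methylation_coupling=-1.0,
        methylation_noise_sd=0.0,
        hotspot_density_per_mb=0.0,
        coupling_scale=20_000,
    ),
    "toy": ScenarioConfig(
        n_chromosomes=2,
        chrom_length=2_000_000,
        snp_spacing=1_000,
        n_domains=8,
        domain_length_range=(50_000, 150_000),
        n_links=60,
        link_distance_range=(5_000, 300_000),
        n_tss_per_chrom=100,
        n_ctcf_per_chrom=60,
    ),
}


@dataclass
class Scenario:
    name: str
    seed: int
    config: ScenarioConfig
    assembly: GenomeAssembly
    gmap: GeneticMap
    domains: list[GenomicInterval]
    hotspots: list[GenomicInterval]
    links: list[Link]
    tracks: list[FeatureTrack]
    ctcf_motifs: list[GenomicInterval]
    methylation: MethylationTrack
    snp_positions: dict[str, np.ndarray]
    tss_positions: dict[str, np.ndarray]
    manifest: dict = field(default_factory=dict)


# --------------------------------------------------------------- genetic map

def _place_nonoverlapping(
    n: int, length_range: tuple[int, int], chrom_len: int, rng: np.random.Generator
) -> np.ndarray:
    """n non-overlapping (start, end) rows, uniform given total feasibility."""
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n)
    slack = chrom_len - int(lengths.sum())
    if slack < 0:
        raise ValueError(
            f"cannot place {n} domains of total length {lengths.sum()} "
            f"on a {chrom_len}-bp chromosome"
        )
    gaps = np.sort(rng.integers(0, slack + 1, size=n))
    starts = gaps + np.concatenate(([0], np.cumsum(lengths[:-1])))
    return np.column_stack((starts, starts + lengths))


def _merge(intervals: np.ndarray) -> np.ndarray:
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    ivs = intervals[np.argsort(intervals[:, 0])]
    out = [ivs[0].tolist()]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def _in_any(sorted_ivs: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Membership of positions in a merged, sorted interval array."""
    if len(sorted_ivs) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(sorted_ivs[:, 0], pos, side="right") - 1
    idx = np.clip(idx, 0, len(sorted_ivs) - 1)
    return (sorted_ivs[idx, 0] <= pos) & (pos < sorted_ivs[idx, 1])


def make_genetic_map(
    config: ScenarioConfig, rng: np.random.Generator
) -> tuple[GeneticMap, list[GenomicInterval], list[GenomicInterval]]:
    """Piecewise-constant landscape with planted valleys and hotspots.

    Per marker interval: rate = baseline x valley multiplier (inside a
    domain) x hotspot multiplier (inside a hotspot); cumulative cM by exact
    integration.
    """
    assembly = config.assembly
    per_chrom = np.full(config.n_chromosomes, config.n_domains // config.n_chromosomes)
    per_chrom[: config.n_domains % config.n_chromosomes] += 1
    positions, cum_cm = {}, {}
    domains, hotspots = [], []
    for ci, (chrom, L) in enumerate(assembly.chromosomes):
        doms = _place_nonoverlapping(int(per_chrom[ci]), config.domain_length_range, L, rng)
        n_hot = rng.poisson(config.hotspot_density_per_mb * L / 1e6)
        hot_mid = rng.integers(config.hotspot_width // 2, L - config.hotspot_width // 2, size=n_hot)
        hots = np.column_stack(
            (hot_mid - config.hotspot_width // 2, hot_mid + config.hotspot_width // 2)
        )
        hots_merged = _merge(hots)
        pos = np.arange(0, L + 1, config.snp_spacing, dtype=np.int64)
        if pos[-1] != L:
            pos = np.append(pos, L)
        mids = (pos[:-1] + pos[1:]) / 2.0
        rate = np.full(len(mids), config.baseline_rate)
        rate[_in_any(doms, mids)] *= config.valley_multiplier
        rate[_in_any(hots_merged, mids)] *= config.hotspot_multiplier
        positions[chrom] = pos
        cum_cm[chrom] = np.concatenate(([0.0], np.cumsum(rate * np.diff(pos) / 1e6)))
        domains.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in doms)
        hotspots.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in hots)
    return GeneticMap(positions, cum_cm), domains, hotspots


# --------------------------------------------------------------------- links

def make_links(
    config: ScenarioConfig,
    domains: list[GenomicInterval],
    assembly: GenomeAssembly,
    rng: np.random.Generator,
) -> list[Link]:
    """Links with 1-bp anchors; a configured fraction fall fully inside domains."""
    d_lo, d_hi = config.link_distance_range
    n_inside = (
        int(round(config.inside_fraction * config.n_links))
        if config.link_placement == "domains"
        else 0
    )
    uniform = config.link_placement == "uniform"
    dom_by_chrom = {
        chrom: _merge(
            np.array([[d.start, d.end] for d in domains if d.chrom == chrom], dtype=np.int64)
        )
        for chrom, _ in assembly.chromosomes
    }
    eligible = [d for d in domains if d.length > d_lo + 1]
    if n_inside > 0 and not eligible:
        raise ValueError("link distance range infeasible for every domain")
    out: list[Link] = []
    for i in range(config.n_links):
        if i < n_inside:
            dom = eligible[int(rng.integers(0, len(eligible)))]
            d = int(rng.integers(d_lo, min(d_hi, dom.length - 2) + 1))
            s = int(rng.integers(dom.start, dom.end - d))
            chrom = dom.chrom
        else:
            chrom_i = int(rng.integers(0, config.n_chromosomes))
            chrom, L = assembly.chromosomes[chrom_i]
            doms = dom_by_chrom[chrom]
            for _ in range(10_000):
                d = int(rng.integers(d_lo, d_hi + 1))
                s = int(rng.integers(0, L - d))
                # span [s, s+d+1) must not intersect any domain
                if uniform or not doms.size or not np.any(
                    (doms[:, 0] < s + d + 1) & (doms[:, 1] > s)
                ):
                    break
            else:
                raise ValueError("could not place a link outside domains")
        score = 10.0 ** (-rng.uniform(4, 12))
        out.append(
            Link(
                GenomicInterval(chrom, s, s + 1),
                GenomicInterval(chrom, s + d, s + d + 1),
                link_type=config.link_type,
                score=score,
                target_id=f"T{i:05d}",
            )
        )
    return out


# -------------------------------------------------------------------- tracks

TRACK_SPECS = {
    # name: (mean, sd, lo clip, hi clip, normalization) in natural units.
    # GC fraction has a natural [0, 1] scale and is normalized by it; the
    # count densities have no natural upper bound, so their normalization
    # constants default to the observed range.
    "gc_percent": (0.41, 0.05, 0.2, 0.8, (0.0, 1.0)),
    "cpg_density": (10.0, 3.0, 0.0, np.inf, None),
    "snp_density": (3.0, 1.0, 0.0, np.inf, None),
    "prdm9_density": (0.2, 0.15, 0.0, np.inf, None),
}


def make_tracks(
    config: ScenarioConfig, assembly: GenomeAssembly, rng: np.random.Generator
) -> list[FeatureTrack]:
    """Spatially autocorrelated feature tracks (moving-average random fields)."""
    w = config.track_smoothness
    tracks = []
    for name, (mean, sd, lo, hi, norm) in TRACK_SPECS.items():
        values = {}
        for chrom, L in assembly.chromosomes:
            n = int(np.ceil(L / config.track_bin_size))
            noise = rng.normal(0.0, sd, size=n)
            if w >= n:
                smooth = np.full(n, noise.mean())
            elif w > 1:
                kernel = np.ones(w) / w
                smooth = np.convolve(noise, kernel, mode="same")
            else:
                smooth = noise
            values[chrom] = np.clip(mean + smooth, lo, hi)
        tracks.append(FeatureTrack(name, config.track_bin_size, values, normalization=norm))
    return tracks


# --------------------------------------------------------------- methylation

def make_methylation(
    config: ScenarioConfig,
    gmap: GeneticMap,
    assembly: GenomeAssembly,
    rng: np.random.Generator,
) -> MethylationTrack:
    """CpG-level methylation coupled to the domain-scale recombination rate.

    The local rate is first smoothed to ``coupling_scale`` (methylation
    tracks domain-scale structure, not individual hotspots); the coupled and
    confounding components are standardized so their 500-kb-window means
    have unit variance, which makes the realized window-level correlation
    approximate the configured coupling rho.
    """
    rho = config.methylation_coupling
    h = config.coupling_scale // 2
    window = 500_000
    positions, levels = {}, {}
    # smooth confounder field shared across the coupling formula
    for chrom, L in assembly.chromosomes:
        pos = np.arange(0, L, config.cpg_spacing, dtype=np.int64)
        pos = pos + rng.integers(0, max(1, config.cpg_spacing // 2), size=len(pos))
        lo = np.clip(pos - h, 0, L).astype(float)
        hi = np.clip(pos + h, 0, L).astype(float)
        r_smooth = interval_rates(gmap, chrom, lo, hi)
        # confounder: coarse Gaussian field, linearly interpolated
        grid = np.arange(0, L + 50_000, 50_000, dtype=float)
        s_field = np.interp(pos.astype(float), grid, rng.normal(0.0, 1.0, size=len(grid)))

        def window_sd(x: np.ndarray) -> float:
            nw = int(np.ceil(L / window))
            idx = np.minimum(pos // window, nw - 1)
            sums = np.bincount(idx, weights=x, minlength=nw)
            cnts = np.bincount(idx, minlength=nw)
            means = sums / np.maximum(cnts, 1)
            sd = float(means[cnts > 0].std(ddof=1)) if (cnts > 0).sum() > 1 else 0.0
            return sd

        sd_r = window_sd(r_smooth)
        sd_s = window_sd(s_field)
        z_r = (r_smooth - r_smooth.mean()) / sd_r if sd_r > 0 else np.zeros(len(pos))
        z_s = s_field / sd_s if sd_s > 0 else np.zeros(len(pos))
        m = (
            config.methylation_mean
            + config.methylation_sd * (rho * z_r + np.sqrt(1 - rho**2) * z_s)
            + rng.normal(0.0, config.methylation_noise_sd, size=len(pos))
        )
        positions[chrom] = pos
        levels[chrom] = np.clip(m, 0.0, 1.0)
    return MethylationTrack(positions, levels)


# ------------------------------------------------------------------ scenario

def make_scenario(name: str, seed: int) -> Scenario:
    """Build a full input bundle for a named preset, deterministically."""
    if name not in PRESETS:
        raise ValueError(f"unknown scenario {name!r}; presets: {sorted(PRESETS)}")
    config = PRESETS[name]
    ss = np.random.SeedSequence(seed)
    r_map, r_links, r_tracks, r_meth, r_points = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    assembly = config.assembly
    gmap, domains, hotspots = make_genetic_map(config, r_map)
    links = make_links(config, domains, assembly, r_links)
    tracks = make_tracks(config, assembly, r_tracks)
    methylation = make_methylation(config, gmap, assembly, r_meth)

    dom_by_chrom = {
        chrom: _merge(
            np.array([[d.start, d.end] for d in domains if d.chrom == chrom], dtype=np.int64)
        )
        for chrom, _ in assembly.chromosomes
    }
    tss_positions, ctcf = {}, []
    for chrom, L in assembly.chromosomes:
        tss_positions[chrom] = np.sort(
            r_points.choice(L, size=config.n_tss_per_chrom, replace=False)
        ).astype(np.int64)
        placed = 0
        while placed < config.n_ctcf_per_chrom:
            s = int(r_points.integers(0, L - config.ctcf_motif_width))
            mid = s + config.ctcf_motif_width // 2
            if not _in_any(dom_by_chrom[chrom], np.array([mid]))[0]:
                ctcf.append(GenomicInterval(chrom, s, s + config.ctcf_motif_width))
                placed += 1
    if config.plant_interrupting_ctcf:
        for ln in links[::2]:
            gap_mid = int((min(ln.anchor_a.end, ln.anchor_b.end)
                           + max(ln.anchor_a.start, ln.anchor_b.start)) // 2)
            w = config.ctcf_motif_width
            if ln.span.length > 2 * w:
                ctcf.append(GenomicInterval(ln.chrom, gap_mid - w // 2, gap_mid - w // 2 + w))

    manifest = {
        "name": name,
        "seed": seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else getattr(v, "value", v))
            for k, v in dataclasses.asdict(config).items()
        },
        "n_domains": len(domains),
        "n_hotspots": len(hotspots),
        "n_links": len(links),
        "n_links_inside": int(round(config.inside_fraction * config.n_links)),
    }
    return Scenario(
        name=name,
        seed=seed,
        config=config,
        assembly=assembly,
        gmap=gmap,
        domains=domains,
        hotspots=hotspots,
        links=links,
        tracks=tracks,
        ctcf_motifs=ctcf,
        methylation=methylation,
        snp_positions={c: gmap.positions[c].copy() for c in gmap.chromosomes},
        tss_positions=tss_positions,
        manifest=manifest,
    )


def write_scenario(scenario: Scenario, outdir) -> dict[str, str]:
    """Write every scenario artifact in standard formats; returns the path map."""
    from . import io as rio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "assembly": "chrom.sizes",
        "genetic_map": "genetic_map.tsv",
        "links": "links.bedpe",
        "domains": "domains.bed",
        "hotspots": "hotspots.bed",
        "ctcf_motifs": "ctcf_motifs.bed",
        "tss": "tss.bed",
        "methylation": "methylation.bedgraph",
        "manifest": "manifest.json",
    }
    rio.write_assembly(scenario.assembly, outdir / paths["assembly"])
    rio.write_genetic_map(scenario.gmap, outdir / paths["genetic_map"])
    rio.write_links(scenario.links, outdir / paths["links"])
    rio.write_intervals(scenario.domains, outdir / paths["domains"])
    rio.write_intervals(scenario.hotspots, outdir / paths["hotspots"])
    rio.write_intervals(scenario.ctcf_motifs, outdir / paths["ctcf_motifs"])
    tss_iv = [
        GenomicInterval(c, int(p), int(p) + 1)
        for c, arr in scenario.tss_positions.items()
        for p in arr
    ]
    rio.write_intervals(tss_iv, outdir / paths["tss"])
    rio.write_methylation(scenario.methylation, outdir / paths["methylation"])
    for t in scenario.tracks:
        paths[f"track_{t.feature_name}"] = f"track_{t.feature_name}.bedgraph"
        rio.write_track(t, outdir / paths[f"track_{t.feature_name}"])
    with open(outdir / paths["manifest"], "w") as fh:
        json.dump(scenario.manifest, fh, indent=2)
    return paths


def load_scenario(directory) -> Scenario:
    """Re-read a written scenario directory into an in-memory bundle."""
    from . import io as rio

    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg_dict = dict(manifest["config"])
    for key in ("domain_length_range", "link_distance_range"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg_dict["link_type"] = LinkType(cfg_dict["link_type"])
    config = ScenarioConfig(**cfg_dict)
    assembly = rio.read_assembly(directory / "chrom.sizes")
    gmap = rio.read_genetic_map(directory / "genetic_map.tsv")
    links = rio.read_links(directory / "links.bedpe", link_type=config.link_type)
    tracks = [
        rio.read_track(p, assembly, bin_size=config.track_bin_size,
                       feature_name=p.stem.removeprefix("track_"))
        for p in sorted(directory.glob("track_*.bedgraph"))
    ]
    tss = rio.read_intervals(directory / "tss.bed", assembly)
    tss_positions: dict[str, list[int]] = {}
    for iv in tss:
        tss_positions.setdefault(iv.chrom, []).append(iv.start)
    return Scenario(
        name=manifest["name"],
        seed=manifest["seed"],
        config=config,
        assembly=assembly,
        gmap=gmap,
        domains=rio.read_intervals(directory / "domains.bed", assembly),
        hotspots=rio.read_intervals(directory / "hotspots.bed", assembly),
        links=links,
        tracks=tracks,
        ctcf_motifs=rio.read_intervals(directory / "ctcf_motifs.bed", assembly),
        methylation=rio.read_methylation(directory / "methylation.bedgraph"),
        snp_positions={c: gmap.positions[c].copy() for c in gmap.chromosomes},
        tss_positions={c: np.array(v, dtype=np.int64) for c, v in tss_positions.items()},
        manifest=manifest,
    )
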