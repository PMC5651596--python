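import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recvalley import (
    GeneticMap,
    GenomicInterval,
    cumulative_cm_at,
    hotspot_density,
    interval_rate,
    interval_rate_masked,
    interval_rates,
    mean_rate_by_distance,
)


class TestCumulativeCm:
    def test_marker_identity(self, toy_map):
        assert cumulative_cm_at(toy_map, "chr1", 2000) == pytest.approx(0.01)

    def test_clamp_before_first(self, toy_map):
        assert cumulative_cm_at(toy_map, "chr1", 10) == pytest.approx(0.0)
        assert cumulative_cm_at(toy_map, "chr1", 999_999) == pytest.approx(0.05)

    def test_linear_interpolation(self, toy_map):
        # halfway between 2000 (0.01) and 4000 (0.05)
        assert cumulative_cm_at(toy_map, "chr1", 3000) == pytest.approx(0.03)

    def test_missing_chromosome(self, toy_map):
        with pytest.raises(KeyError):
            cumulative_cm_at(toy_map, "chrX", 0)


class TestIntervalRate:
    def test_constant_landscape(self):
        gmap = GeneticMap(
            {"chr1": np.array([0, 1_000_000])}, {"chr1": np.array([0.0, 2.5])}
        )
        for s, e in [(0, 1000), (100, 777_000), (999_000, 1_000_000)]:
            rate, covered = interval_rate(gmap, GenomicInterval("chr1", s, e))
            assert rate == pytest.approx(2.5)
            assert covered

    def test_hand_interpolated_interval(self, toy_map):
        # cm(3000)=0.03, cm(1500)=0.005 -> 0.025 cM over 1.5 kb
        rate, _ = interval_rate(toy_map, GenomicInterval("chr1", 1500, 3000))
        assert rate == pytest.approx(0.025 / (1500 / 1e6))
        assert rate == pytest.approx(16.6667, rel=1e-4)

    def test_whole_range_telescopes(self, toy_map):
        rate, _ = interval_rate(toy_map, GenomicInterval("chr1", 1000, 4000))
        assert rate == pytest.approx(0.05 / (3000 / 1e6))

    def test_no_coverage_flag(self, toy_map):
        rate, covered = interval_rate(toy_map, GenomicInterval("chr1", 5000, 6000))
        assert rate == 0.0
        assert not covered

    def test_brute_force_oracle(self):
        """interval_rate agrees with explicit per-marker-interval summation."""
        rng = np.random.default_rng(42)
        pos = np.sort(rng.choice(5_000_000, size=300, replace=False))
        rates = rng.uniform(0, 8, size=299)
        cum = np.concatenate(([0.0], np.cumsum(rates * np.diff(pos) / 1e6)))
        gmap = GeneticMap({"chr1": pos}, {"chr1": cum})
        for _ in range(1000):
            s = int(rng.integers(pos[0], pos[-1] - 1))
            e = int(rng.integers(s + 1, pos[-1] + 1))
            # oracle: sum rate x overlap over every marker interval
            cm = 0.0
            for i in range(len(pos) - 1):
                ov = max(0, min(e, pos[i + 1]) - max(s, pos[i]))
                cm += rates[i] * ov / 1e6
            expected = cm / ((e - s) / 1e6)
            got, _ = interval_rate(gmap, GenomicInterval("chr1", s, e))
            assert got == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 96), st.integers(1, 50), st.integers(1, 50))
    def test_additivity(self, start, la, lb):
        rng = np.random.default_rng(start * 1000 + la + lb)
        pos = np.arange(0, 101) * 1000
        rates = rng.uniform(0, 5, size=100)
        cum = np.concatenate(([0.0], np.cumsum(rates * 1000 / 1e6)))
        gmap = GeneticMap({"chr1": pos}, {"chr1": cum})
        a = GenomicInterval("chr1", start * 1000, start * 1000 + la * 10)
        b = GenomicInterval("chr1", a.end, a.end + lb * 10)
        union = GenomicInterval("chr1", a.start, b.end)
        ra, _ = interval_rate(gmap, a)
        rb, _ = interval_rate(gmap, b)
        ru, _ = interval_rate(gmap, union)
        weighted = (ra * a.length + rb * b.length) / union.length
        assert ru == pytest.approx(weighted, abs=1e-9)


class TestMaskedRate:
    def test_empty_mask_identity(self, toy_map):
        iv = GenomicInterval("chr1", 1500, 3000)
        assert interval_rate_masked(toy_map, iv, []) == pytest.approx(
            interval_rate(toy_map, iv)[0]
        )

    def test_constant_landscape_invariant(self):
        gmap = GeneticMap(
            {"chr1": np.array([0, 1_000_000])}, {"chr1": np.array([0.0, 3.0])}
        )
        iv = GenomicInterval("chr1", 0, 100_000)
        masked = interval_rate_masked(gmap, iv, [GenomicInterval("chr1", 20_000, 70_000)])
        assert masked == pytest.approx(3.0)

    def test_two_segment_landscape(self):
        # 1 cM/Mb on the first Mb, 3 cM/Mb on the second; mask the 3 cM/Mb half
        pos = np.array([0, 1_000_000, 2_000_000])
        cum = np.array([0.0, 1.0, 4.0])
        gmap = GeneticMap({"chr1": pos}, {"chr1": cum})
        iv = GenomicInterval("chr1", 0, 2_000_000)
        masked = interval_rate_masked(
            gmap, iv, [GenomicInterval("chr1", 1_000_000, 2_000_000)]
        )
        assert masked == pytest.approx(1.0)

    def test_fully_masked_is_nan(self, toy_map):
        iv = GenomicInterval("chr1", 1000, 2000)
        assert np.isnan(interval_rate_masked(toy_map, iv, [iv]))


class TestMeanRateByDistance:
    def test_constant_rate_zero_ci(self, make_point_link):
        gmap = GeneticMap(
            {"chr1": np.array([0, 10_000_000])}, {"chr1": np.array([0.0, 20.0])}
        )
        links = [make_point_link("chr1", 1000 * i, 1000 * i + 50_000) for i in range(50)]
        df = mean_rate_by_distance(links, gmap, n_bins=10)
        occupied = df[df["n"] > 0]
        assert np.allclose(occupied["mean_rate"], 2.0)
        assert np.allclose(occupied["ci_halfwidth"], 0.0)

    def test_singleton_bin_zero_halfwidth(self, make_point_link):
        gmap = GeneticMap(
            {"chr1": np.array([0, 10_000_000])}, {"chr1": np.array([0.0, 20.0])}
        )
        df = mean_rate_by_distance([make_point_link("chr1", 0, 50_000)], gmap, n_bins=5)
        row = df[(df["distance_class"] == "MEDIUM") & (df["n"] == 1)]
        assert len(row) == 1
        assert row["ci_halfwidth"].iloc[0] == 0.0

    def test_two_links_formula(self, make_point_link):
        # rates 1 and 3 in the same bin: mean 2, half-width sd(1,3) * 1.96/10
        pos = np.array([0, 50_001, 100_000, 150_001])
        cum = np.array([0.0, 0.050001, 0.050001, 0.050001 + 3 * 0.050001])
        gmap = GeneticMap({"chr1": pos}, {"chr1": cum})
        links = [
            make_point_link("chr1", 0, 50_000),
            make_point_link("chr1", 100_000, 150_000),
        ]
        df = mean_rate_by_distance(links, gmap, n_bins=1)
        row = df[df["n"] == 2].iloc[0]
        assert row["mean_rate"] == pytest.approx(2.0, rel=1e-4)
        assert row["ci_halfwidth"] == pytest.approx(
            np.std([1.0, 3.0], ddof=1) * 1.96 / 10, rel=1e-4
        )

    def test_empty_input_rejected(self, toy_map):
        with pytest.raises(ValueError):
            mean_rate_by_distance([], toy_map)


class TestHotspotDensity:
    def test_no_hotspots(self):
        assert hotspot_density(GenomicInterval("chr1", 0, 100_000), []) == 0.0

    def test_two_in_100kb(self):
        iv = GenomicInterval("chr1", 0, 100_000)
        hs = [
            GenomicInterval("chr1", 10_000, 12_000),
            GenomicInterval("chr1", 50_000, 52_000),
            GenomicInterval("chr1", 99_500, 101_500),  # midpoint outside
            GenomicInterval("chr2", 10_000, 12_000),
        ]
        assert hotspot_density(iv, hs) == pytest.approx(0.02)

    def test_threshold_partitions(self, toy_scenario):
        links = toy_scenario.links
        dens = [hotspot_density(ln.span, toy_scenario.hotspots) for ln in links]
        below = [ln for ln, d in zip(links, dens) if d < 0.005]
        above = [ln for ln, d in zip(links, dens) if d >= 0.005]
        assert len(below) + len(above) == len(links)
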