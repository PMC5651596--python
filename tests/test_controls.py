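import numpy as np
import pytest
from scipy import stats as sps

from recvalley import GenomeAssembly, GenomicInterval, Link
from recvalley.controls import (
    NullPairUniverse,
    build_candidate_index,
    sample_feature_matched_rejection,
    sample_kdtree_matched,
    sample_length_matched,
    sample_null_pairs,
    sample_within_domain,
)
from recvalley.genome import DistanceClass
from recvalley.tracks import FeatureTrack


def span_link(chrom, start, end):
    return Link(
        GenomicInterval(chrom, start, start + 1), GenomicInterval(chrom, end - 1, end)
    )


def flat_track(name, assembly, value=1.0, bin_size=1_000):
    return FeatureTrack(
        name,
        bin_size,
        {
            c: np.full(int(np.ceil(L / bin_size)), value)
            for c, L in assembly.chromosomes
        },
        normalization=(0.0, 1.0),
    )


class TestLengthMatched:
    def test_forced_unique_interval(self):
        asm = GenomeAssembly((("chr1", 10_000),))
        ctrl = sample_length_matched(span_link("chr1", 2_000, 12_000 - 2_000 + 2_000), asm, np.random.default_rng(0))
        # span length equals chromosome length -> only [0, L)
        link = span_link("chr1", 0, 10_000)
        ctrl = sample_length_matched(link, asm, np.random.default_rng(0))
        assert (ctrl.start, ctrl.end) == (0, 10_000)

    def test_span_longer_than_chromosome_rejected(self):
        asm = GenomeAssembly((("chr1", 10_000),))
        with pytest.raises(ValueError):
            sample_length_matched(span_link("chr1", 0, 20_000), asm, np.random.default_rng(0))

    def test_start_distribution_uniform(self):
        asm = GenomeAssembly((("chr1", 10_000_000),))
        link = span_link("chr1", 0, 100_000)
        rng = np.random.default_rng(123)
        starts = np.array(
            [sample_length_matched(link, asm, rng).start for _ in range(10_000)]
        )
        stat = sps.kstest(starts / (10_000_000 - 100_000), "uniform")
        assert stat.pvalue > 0.01
        assert all(
            sample_length_matched(link, asm, rng).length == 100_000 for _ in range(50)
        )


class TestRejectionSampler:
    asm = GenomeAssembly((("chr1", 200_000),))

    def test_constant_tracks_first_draw(self):
        tracks = [flat_track("gc", self.asm, 0.4)]
        pair = sample_feature_matched_rejection(
            span_link("chr1", 0, 10_000), tracks, self.asm, np.random.default_rng(0)
        )
        assert pair.matched and pair.iterations == 1
        assert pair.feature_distance < 1e-9

    def test_engineered_single_window(self):
        # feature = 1 only on [5k,15k) (the link) and [100k,110k); within the
        # 0.01 tolerance a control must start within ~100 bp of either window
        vals = np.zeros(200)
        vals[5:15] = 1.0
        vals[100:110] = 1.0
        track = FeatureTrack("f", 1_000, {"chr1": vals}, normalization=(0.0, 1.0))
        link = span_link("chr1", 5_000, 15_000)
        rng = np.random.default_rng(7)
        for _ in range(100):
            pair = sample_feature_matched_rejection(link, [track], self.asm, rng)
            assert pair.matched
            assert min(abs(pair.control.start - 5_000), abs(pair.control.start - 100_000)) <= 100

    def test_zero_tolerance_exhausts(self):
        rng = np.random.default_rng(1)
        vals = np.arange(200, dtype=float)  # no two intervals share a mean
        track = FeatureTrack("f", 1_000, {"chr1": vals})
        pair = sample_feature_matched_rejection(
            span_link("chr1", 0, 10_000), [track], self.asm, rng,
            tolerance=0.0, max_iter=500,
        )
        assert not pair.matched and pair.iterations == 500
        assert pair.control.length == 10_000

    def test_no_tracks_degrades_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            pair = sample_feature_matched_rejection(
                span_link("chr1", 0, 10_000), [], self.asm, np.random.default_rng(0)
            )
        assert pair.matched and "length matching" in caplog.text

    def test_acceptance_monotone_in_tolerance(self):
        rng0 = np.random.default_rng(3)
        vals = rng0.normal(0.5, 0.2, size=200)
        track = FeatureTrack("f", 1_000, {"chr1": vals})
        link = span_link("chr1", 40_000, 52_000)
        matched = []
        for tol in (1e-4, 1e-3, 1e-2, 1e-1):
            rng = np.random.default_rng(99)
            n = sum(
                sample_feature_matched_rejection(
                    link, [track], self.asm, rng, tolerance=tol, max_iter=300
                ).matched
                for _ in range(30)
            )
            matched.append(n)
        assert matched == sorted(matched)


class TestCandidateIndex:
    asm = GenomeAssembly((("chr1", 1_000_000),))

    def make_index(self, **kw):
        tracks = [
            FeatureTrack(
                "f", 1_000, {"chr1": np.sin(np.arange(1000) / 7.0)}, normalization=(-1, 1)
            )
        ]
        return build_candidate_index(
            self.asm, tracks, length_min=1_000, length_max=100_000, **kw
        )

    def test_candidate_count_formula(self):
        idx = self.make_index()
        # sum over lengths 1k..100k of ((1e6 - l) / 1000 + 1)
        expected = sum((1_000_000 - l) // 1_000 + 1 for l in range(1_000, 100_001, 1_000))
        assert idx.n_candidates == expected
        assert expected <= 100_000
        assert np.all(idx.starts + idx.lengths <= 1_000_000)

    def test_memory_guard(self):
        with pytest.raises(MemoryError, match="subsample"):
            self.make_index(max_candidates=10_000)

    def test_guard_satisfied_by_subsampling(self):
        idx = self.make_index(max_candidates=10_000, subsample=20)
        assert idx.n_candidates <= 10_000

    def test_query_saturates_at_candidate_count(self):
        idx = self.make_index(subsample=50)
        link = span_link("chr1", 200_000, 260_000)
        ctrl = sample_kdtree_matched(idx, link, np.random.default_rng(0), k=10**9)
        assert isinstance(ctrl, GenomicInterval)

    def test_knn_equals_brute_force(self):
        """Tree k-NN distances match an exhaustive scan for 100 queries."""
        idx = self.make_index(subsample=10)  # <= 10^4 candidates
        assert idx.n_candidates <= 10_000
        rng = np.random.default_rng(5)
        for _ in range(100):
            s = int(rng.integers(0, 900_000))
            link = span_link("chr1", s, s + int(rng.integers(2_000, 90_000)))
            q = idx.link_features(link)
            d_tree, _ = idx.tree.query(q, k=50)
            brute = np.sort(np.sqrt(((idx.features - q) ** 2).sum(axis=1)))[:50]
            np.testing.assert_allclose(np.sort(d_tree), brute, atol=1e-9)


class TestKdtreeFilters:
    def test_overlap_rule_60_vs_40(self):
        # constant features: every candidate equidistant; the overlap filter
        # alone decides eligibility
        asm = GenomeAssembly((("chr1", 100_000),))
        tracks = [flat_track("f", asm)]
        idx = build_candidate_index(asm, tracks, grid=1_000, length_min=10_000, length_max=10_000)
        link = span_link("chr1", 50_000, 60_000)
        rng = np.random.default_rng(0)
        seen = {sample_kdtree_matched(idx, link, rng, k=idx.n_candidates).start for _ in range(300)}
        # candidates overlapping more than 50% of 10 kb (starts 46..54 kb ->
        # overlap 6..10 kb) excluded; exactly 50% (45/55 kb) and 40% (44/56 kb)
        # eligible
        assert 44_000 in seen and 56_000 in seen
        assert all(not (46_000 <= s <= 54_000) for s in seen)

    def test_ctcf_exclusion(self):
        asm = GenomeAssembly((("chr1", 100_000),))
        tracks = [flat_track("f", asm)]
        idx = build_candidate_index(asm, tracks, grid=1_000, length_min=5_000, length_max=5_000)
        motifs = [GenomicInterval("chr1", s, s + 19) for s in range(500, 50_000, 1_000)]
        link = span_link("chr1", 60_000, 65_000)
        rng = np.random.default_rng(1)
        for _ in range(100):
            ctrl = sample_kdtree_matched(idx, link, rng, k=idx.n_candidates, ctcf_motifs=motifs)
            assert all(ctrl.overlap(m) == 0 for m in motifs)

    def test_all_filtered_raises(self):
        asm = GenomeAssembly((("chr1", 20_000),))
        tracks = [flat_track("f", asm)]
        idx = build_candidate_index(asm, tracks, grid=1_000, length_min=18_000, length_max=18_000)
        link = span_link("chr1", 1_000, 19_000)
        with pytest.raises(RuntimeError, match="filtered"):
            sample_kdtree_matched(idx, link, np.random.default_rng(0), k=idx.n_candidates)


class TestDomainSampler:
    def test_domain_equals_span_forced(self):
        dom = GenomicInterval("chr1", 10_000, 20_000)
        ctrl = sample_within_domain(span_link("chr1", 10_000, 20_000), [dom], np.random.default_rng(0))
        assert (ctrl.start, ctrl.end) == (10_000, 20_000)

    def test_no_containing_domain_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            out = sample_within_domain(
                span_link("chr1", 0, 10_000),
                [GenomicInterval("chr1", 50_000, 80_000)],
                np.random.default_rng(0),
            )
        assert out is None

    def test_containment_property(self):
        dom = GenomicInterval("chr1", 100_000, 400_000)
        link = span_link("chr1", 150_000, 250_000)
        rng = np.random.default_rng(2)
        for _ in range(1_000):
            ctrl = sample_within_domain(link, [dom], rng)
            assert dom.contains(ctrl) and ctrl.length == link.span.length

    def test_uniform_within_double_length_domain(self):
        dom = GenomicInterval("chr1", 0, 200_000)
        link = span_link("chr1", 10_000, 110_000)
        rng = np.random.default_rng(3)
        starts = np.array(
            [sample_within_domain(link, [dom], rng).start for _ in range(5_000)]
        )
        assert sps.kstest(starts / 100_000, "uniform").pvalue > 0.01


class TestNullPairs:
    def test_single_feasible_pair(self):
        out = sample_null_pairs(
            {"chr1": np.array([0])},
            {"chr1": np.array([50_000])},
            10,
            DistanceClass.MEDIUM,
            np.random.default_rng(0),
        )
        assert all(iv == GenomicInterval("chr1", 0, 50_001) for iv in out)

    def test_distances_in_class(self):
        rng = np.random.default_rng(4)
        a = {"chr1": np.sort(rng.choice(2_000_000, 300, replace=False))}
        b = {"chr1": np.sort(rng.choice(2_000_000, 100, replace=False))}
        for cls, lo, hi in [
            (DistanceClass.SHORT, 1_000, 10_000),
            (DistanceClass.MEDIUM, 10_000, 100_000),
            (DistanceClass.LONG, 100_000, 1_000_000),
        ]:
            for iv in sample_null_pairs(a, b, 500, cls, rng):
                d = iv.length - 1
                assert lo <= d <= hi
                if cls != DistanceClass.LONG:
                    assert d < hi

    def test_no_feasible_pair_raises(self):
        with pytest.raises(ValueError, match="SHORT"):
            NullPairUniverse(
                {"chr1": np.array([0])}, {"chr1": np.array([500_000])}, DistanceClass.SHORT
            )

    def test_uniformity_against_enumeration(self):
        """Sampling frequencies match the fully enumerated pair universe."""
        rng = np.random.default_rng(11)
        a = {"chr1": np.sort(rng.choice(500_000, 20, replace=False))}
        b = {"chr1": np.sort(rng.choice(500_000, 5, replace=False))}
        uni = NullPairUniverse(a, b, DistanceClass.MEDIUM)
        pairs = uni.enumerate_pairs()
        assert uni.total_pairs == len(pairs)
        draws = uni.sample(50_000, rng)
        counts = {p: 0 for p in pairs}
        for d in draws:
            counts[d] += 1
        chi = sps.chisquare(list(counts.values()))
        assert chi.pvalue > 0.01
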