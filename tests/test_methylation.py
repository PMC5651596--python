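import numpy as np
import pandas as pd
import pytest

from recvalley import (
    GeneticMap,
    GenomeAssembly,
    GenomicInterval,
    Link,
    depletion_recapitulation,
    interval_feature_table,
    quantile_rate_profile,
    window_correlation,
)
from recvalley.methylation import MISSING_METH, RatePredictor
from recvalley.tracks import FeatureTrack, MethylationTrack


def track_from(values, bin_size=1_000):
    return FeatureTrack("t", bin_size, {"chr1": np.asarray(values, dtype=float)})


class TestWindowCorrelation:
    asm = GenomeAssembly((("chr1", 4_000),))

    def test_self_correlation_is_one(self):
        t = track_from([1.0, 2.0, 3.0, 4.0])
        r, _, n = window_correlation(t, t, self.asm, window=1_000)
        assert r == pytest.approx(1.0) and n == 4

    def test_negated_correlation_is_minus_one(self):
        x = track_from([1.0, 2.0, 3.0, 4.0])
        y = track_from([-1.0, -2.0, -3.0, -4.0])
        r, _, _ = window_correlation(x, y, self.asm, window=1_000)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        x = track_from([1.0, 2.0, 3.0, 4.0])
        y = track_from([2.0, 1.0, 4.0, 3.0])
        r, _, _ = window_correlation(x, y, self.asm, window=1_000)
        assert r == pytest.approx(0.6)

    def test_symmetry(self):
        x = track_from([1.0, 2.0, 3.0, 4.0])
        y = track_from([2.0, 1.0, 4.0, 3.0])
        assert window_correlation(x, y, self.asm, window=1_000)[0] == pytest.approx(
            window_correlation(y, x, self.asm, window=1_000)[0]
        )

    def test_too_few_windows_rejected(self):
        t = track_from([1.0, 2.0])
        with pytest.raises(ValueError, match="windows"):
            window_correlation(t, t, GenomeAssembly((("chr1", 2_000),)), window=1_000)

    def test_spearman_method(self):
        x = track_from([1.0, 2.0, 3.0, 4.0])
        y = track_from([1.0, 4.0, 9.0, 16.0])  # monotone transform
        r, _, _ = window_correlation(x, y, self.asm, window=1_000, method="spearman")
        assert r == pytest.approx(1.0)


def blockwise_setup(n_blocks=20, block=10_000):
    """Map where block i has rate 2 - m_i and methylation level m_i."""
    rng = np.random.default_rng(0)
    m = rng.uniform(0.1, 0.9, size=n_blocks)
    L = n_blocks * block
    pos = np.arange(0, L + 1, block)
    rates = 2.0 - m
    cum = np.concatenate(([0.0], np.cumsum(rates * block / 1e6)))
    gmap = GeneticMap({"chr1": pos}, {"chr1": cum})
    cpg_pos, cpg_lev = [], []
    for i in range(n_blocks):
        ps = np.arange(i * block, (i + 1) * block, 500)
        cpg_pos.append(ps)
        cpg_lev.append(np.full(len(ps), m[i]))
    meth = MethylationTrack(
        {"chr1": np.concatenate(cpg_pos)}, {"chr1": np.concatenate(cpg_lev)}
    )
    links = [
        Link(
            GenomicInterval("chr1", i * block + 100, i * block + 101),
            GenomicInterval("chr1", i * block + 8_000, i * block + 8_001),
        )
        for i in range(n_blocks)
    ]
    return gmap, meth, links, m


class TestQuantileProfile:
    def test_monotone_coupling_gives_decreasing_means(self):
        gmap, meth, links, _ = blockwise_setup()
        df = quantile_rate_profile(links, meth, gmap, n_quantiles=5)
        means = df["mean_rate"].to_numpy()
        assert np.all(np.diff(means) < 0)

    def test_counts_partition_links(self):
        gmap, meth, links, _ = blockwise_setup()
        df = quantile_rate_profile(links, meth, gmap, n_quantiles=4)
        assert df["n"].sum() == len(links)

    def test_identical_methylation_single_bin(self, toy_map):
        meth = MethylationTrack(
            {"chr1": np.array([1_100, 1_200, 2_500])}, {"chr1": np.full(3, 0.5)}
        )
        links = [
            Link(GenomicInterval("chr1", 1_000, 1_001), GenomicInterval("chr1", 3_000, 3_001)),
            Link(GenomicInterval("chr1", 1_050, 1_051), GenomicInterval("chr1", 3_100, 3_101)),
        ]
        df = quantile_rate_profile(links, meth, toy_map, n_quantiles=2)
        assert (df["n"] > 0).sum() == 1
        assert df.loc[df["n"] > 0, "quantile"].iloc[0] == 0  # ties -> lowest quantile

    def test_fewer_links_than_quantiles_rejected(self, toy_map):
        gmap, meth, links, _ = blockwise_setup(n_blocks=4)
        with pytest.raises(ValueError):
            quantile_rate_profile(links, meth, gmap, n_quantiles=10)


class TestFeatureTable:
    asm = GenomeAssembly((("chr1", 1_000_000),))

    def links_at(self, *spans):
        return [
            Link(GenomicInterval("chr1", s, s + 1), GenomicInterval("chr1", e - 1, e))
            for s, e in spans
        ]

    def test_full_overlap(self):
        links = self.links_at((10_000, 100_000))
        df = interval_feature_table(
            [GenomicInterval("chr1", 20_000, 50_000)], {"eQTL": links}, None, self.asm
        )
        assert df["overlap_eQTL"].iloc[0] == pytest.approx(1.0)

    def test_half_coverage(self):
        links = self.links_at((0, 50_000))
        df = interval_feature_table(
            [GenomicInterval("chr1", 0, 100_000)], {"HiC": links}, None, self.asm
        )
        assert df["overlap_HiC"].iloc[0] == pytest.approx(0.5)

    def test_absent_type_zero_and_missing_meth_flag(self):
        meth = MethylationTrack({"chr1": np.array([900_000])}, {"chr1": np.array([0.5])})
        df = interval_feature_table(
            [GenomicInterval("chr1", 0, 10_000)],
            {"eQTL": []},
            meth,
            self.asm,
        )
        assert df["overlap_eQTL"].iloc[0] == 0.0
        assert df["methylation"].iloc[0] == MISSING_METH


class TestRatePredictor:
    def make_data(self, n=200, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        meth = rng.uniform(0, 1, size=n)
        feats = pd.DataFrame(
            {
                "chrom": rng.integers(0, 2, size=n),
                "length": rng.integers(10_000, 100_000, size=n),
                "methylation": meth,
            }
        )
        rates = 2.0 - meth + rng.normal(0, noise, size=n)
        return feats, rates

    def test_deterministic_signal_recovered(self):
        feats, rates = self.make_data()
        res = RatePredictor(feats, rates).fit(n_trees=100, seed=1)
        assert res.cv_pearson > 0.95

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(2)
        feats, _ = self.make_data(n=1_000, seed=2)
        rates = rng.normal(size=1_000)
        res = RatePredictor(feats, rates).fit(n_trees=100, seed=2)
        assert abs(res.cv_pearson) < 0.1

    def test_bit_reproducible(self):
        feats, rates = self.make_data()
        a = RatePredictor(feats, rates).fit(n_trees=50, seed=3)
        b = RatePredictor(feats, rates).fit(n_trees=50, seed=3)
        assert a.cv_pearson == b.cv_pearson and a.cv_mse == b.cv_mse
        np.testing.assert_array_equal(a.oof_predictions, b.oof_predictions)

    def test_constant_target_flagged(self):
        feats, _ = self.make_data(n=60)
        res = RatePredictor(feats, np.ones(60)).fit(n_trees=20, seed=0)
        assert np.isnan(res.cv_pearson)
        assert res.cv_mse == pytest.approx(0.0)

    def test_too_few_rows_rejected(self):
        feats, rates = self.make_data(n=200)
        with pytest.raises(ValueError):
            RatePredictor(feats.head(10), rates[:10])

    def test_summary_reports_metrics(self):
        feats, rates = self.make_data(n=60)
        res = RatePredictor(feats, rates).fit(n_trees=20, seed=0)
        assert "Pearson" in res.summary() and "MSE" in res.summary()


class TestDepletionRecapitulation:
    def test_perfect_oracle_is_one(self):
        obs_l, obs_c = [0.5, 0.6], [1.0, 1.1]
        raw, clipped = depletion_recapitulation(obs_l, obs_c, obs_l, obs_c)
        assert raw == pytest.approx(1.0) and clipped == 1.0

    def test_constant_predictor_is_zero(self):
        raw, clipped = depletion_recapitulation([0.8, 0.8], [0.8, 0.8], [0.5], [1.0])
        assert raw == 0.0 and clipped == 0.0

    def test_zero_observed_difference_flagged(self):
        raw, clipped = depletion_recapitulation([0.1], [0.9], [1.0], [1.0])
        assert np.isnan(raw) and np.isnan(clipped)
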