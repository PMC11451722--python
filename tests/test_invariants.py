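import numpy as np
import pytest

import neurodyn as nd
from neurodyn.invariants import (DEFAULT_MEASURES, DegenerateSeriesError,
                                 FeatureConfig, approximate_entropy,
                                 correlation_dimension, dfa, hurst_rs,
                                 lyapunov_max, permutation_entropy,
                                 sample_entropy)

from _oracles import (approximate_entropy_direct, permutation_entropy_direct,
                      sample_entropy_direct)


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.ones(100)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed,n", [(0, 150), (1, 200), (2, 120)])
    def test_matches_direct_template_count(self, seed, n):
        x = np.random.default_rng(seed).standard_normal(n)
        got = sample_entropy(x, m=2, r=0.2)
        expected = sample_entropy_direct(x, m=2, r=0.2)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_sine_less_complex_than_noise(self):
        t = np.arange(1500) / 100.0
        sine = np.sin(2 * np.pi * 5 * t)
        noise = np.random.default_rng(3).standard_normal(1500)
        assert sample_entropy(sine) < sample_entropy(noise)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.arange(3.0), m=2)


class TestEntropyVariants:
    def test_approximate_entropy_of_constant_is_zero(self):
        assert approximate_entropy(np.ones(80)) == pytest.approx(0.0,
                                                                 abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_approximate_entropy_matches_direct(self, seed):
        x = np.random.default_rng(seed).standard_normal(120)
        assert approximate_entropy(x, 2, 0.2) == pytest.approx(
            approximate_entropy_direct(x, 2, 0.2), abs=1e-12)

    def test_monotone_series_has_single_pattern(self):
        assert permutation_entropy(np.arange(50.0), order=3) == 0.0

    def test_uniform_noise_saturates_pattern_entropy(self):
        u = np.random.default_rng(2).uniform(size=10_000)
        h = permutation_entropy(u, order=3)
        assert h == pytest.approx(np.log(6), rel=0.02)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_permutation_entropy_matches_direct(self, seed):
        # includes ties: discretized values
        x = np.round(np.random.default_rng(seed).standard_normal(300), 1)
        assert permutation_entropy(x, order=3) == pytest.approx(
            permutation_entropy_direct(x, 3), abs=1e-12)

    def test_normalized_in_unit_interval(self):
        u = np.random.default_rng(5).uniform(size=2000)
        h = permutation_entropy(u, order=4, normalize=True)
        assert 0.0 < h <= 1.0


class TestCorrelationDimension:
    def test_line_has_dimension_one(self):
        x = np.linspace(0.0, 1.0, 1000)
        assert correlation_dimension(x, m=3, tau=1) == pytest.approx(1.0,
                                                                     abs=0.1)

    def test_lorenz_attractor_near_two(self, lorenz_x):
        d2 = correlation_dimension(lorenz_x, m=5, tau=31)
        assert d2 == pytest.approx(2.05, abs=0.2)

    def test_noise_estimate_grows_with_embedding(self):
        x = np.random.default_rng(0).standard_normal(3000)
        assert correlation_dimension(x, m=6, tau=1) > \
            correlation_dimension(x, m=3, tau=1)

    def test_degenerate_input_flagged(self):
        with pytest.raises((DegenerateSeriesError, ValueError)):
            correlation_dimension(np.zeros(500), m=3, tau=1)


class TestDFA:
    def test_white_noise_exponent_half(self):
        x = np.random.default_rng(1).standard_normal(10_000)
        assert dfa(x) == pytest.approx(0.5, abs=0.05)

    def test_brownian_profile_three_halves(self):
        x = np.random.default_rng(1).standard_normal(10_000)
        assert dfa(np.cumsum(x)) == pytest.approx(1.5, abs=0.1)

    def test_monotone_in_hurst(self):
        a = dfa(nd.generate_fgn(0.8, 10_000, seed=2))
        b = dfa(nd.generate_fgn(0.2, 10_000, seed=2))
        assert a > b

    def test_scale_validation(self):
        with pytest.raises(ValueError):
            dfa(np.random.default_rng(0).standard_normal(100),
                scales=np.array([4, 8, 16, 64]))


class TestHurst:
    def test_white_noise_mean_half(self):
        hs = [hurst_rs(np.random.default_rng(s).standard_normal(10_000))
              for s in range(20)]
        assert np.mean(hs) == pytest.approx(0.5, abs=0.05)

    def test_fgn_target_recovered(self):
        assert hurst_rs(nd.generate_fgn(0.8, 10_000, seed=5)) == \
            pytest.approx(0.8, abs=0.1)

    def test_persistence_ordering(self):
        h_hi = hurst_rs(nd.generate_fgn(0.8, 10_000, seed=6))
        h_lo = hurst_rs(nd.generate_fgn(0.2, 10_000, seed=6))
        assert h_hi > 0.5 > h_lo

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            hurst_rs(np.random.default_rng(0).standard_normal(100))


class TestLyapunov:
    def test_fully_chaotic_logistic_map(self):
        x = nd.generate_system(nd.SystemSpec(
            "logistic", {"r": 4.0, "x0": 0.3}, n_samples=2000)).data[0]
        lam = lyapunov_max(x, m=2, tau=1, fs=1.0)
        assert lam == pytest.approx(np.log(2), rel=0.15)

    def test_lorenz_standard_benchmark(self, lorenz_x):
        lam = lyapunov_max(lorenz_x, m=3, tau=31, fs=100.0)
        assert lam == pytest.approx(0.9, rel=0.25)

    def test_periodic_signal_shows_no_divergence(self):
        t = np.arange(2000) / 250.0
        lam = lyapunov_max(np.sin(2 * np.pi * 10 * t), m=3, tau=6, fs=250.0)
        # a pure oscillation has a zero largest exponent; the estimate must
        # sit far below any chaotic scale
        assert lam < 0.05

    def test_identical_points_flagged(self):
        with pytest.raises(DegenerateSeriesError):
            lyapunov_max(np.zeros(500), m=2, tau=1)


class TestExtractFeatures:
    def test_default_set_has_fifteen_measures(self):
        assert len(DEFAULT_MEASURES) == 15

    def test_value_count_small_recording(self, tiny_cohort):
        recs, _ = tiny_cohort
        cfg = FeatureConfig(rqa_max_points=200)
        table = nd.extract_features(recs[0], cfg)
        n_ch, n_bands = recs[0].n_channels, cfg.n_bands
        assert len(table) == n_ch * n_bands
        meas_cols = [c for c in table.columns
                     if c not in ("channel", "band")
                     and not c.startswith("flag_")]
        assert len(meas_cols) == 15
        # every value is finite (flag convention: placeholders are 0)
        assert np.isfinite(table[meas_cols].to_numpy()).all()

    def test_power_only_config_equals_band_power(self, tiny_cohort):
        recs, _ = tiny_cohort
        cfg = FeatureConfig(measures=["power"])
        table = nd.extract_features(recs[0], cfg)
        bs = nd.to_band_signals(recs[0].data[0], recs[0].fs, cfg.n_bands)
        row = table[(table.channel == recs[0].ch_names[0])
                    & (table.band == bs.names[0])]
        assert row["power"].iloc[0] == pytest.approx(
            nd.band_power(bs.series(bs.names[0])))

    def test_rerun_is_deterministic(self, tiny_cohort):
        recs, _ = tiny_cohort
        cfg = FeatureConfig(rqa_max_points=150)
        t1 = nd.extract_features(recs[1], cfg)
        t2 = nd.extract_features(recs[1], cfg)
        assert t1.equals(t2)

    def test_short_channel_flagged_not_dropped(self):
        rec = nd.Recording(np.random.default_rng(0).standard_normal((1, 128)),
                           fs=64.0, ch_names=["c1"])
        cfg = FeatureConfig(min_series_len=256)
        table = nd.extract_features(rec, cfg)
        flag_cols = [c for c in table.columns if c.startswith("flag_")]
        assert table[flag_cols].to_numpy().all()

    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError):
            FeatureConfig(measures=["power", "nosuch"])
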