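import numpy as np
import pytest

from oxiscreen.features import (APNEA_BAND, FEATURE_NAMES, band_powers,
                                central_tendency_measure, extract_features,
                                freq_moments, lempel_ziv_complexity,
                                lz76_phrase_count, median_frequency,
                                sample_entropy, segment_signal,
                                spectral_entropy, SpectralEstimate,
                                time_moments, welch_psd)
from oracles import (ctm_bruteforce, moments_bruteforce, sampen_bruteforce)


class TestSegmentation:
    @pytest.mark.parametrize("n,expected", [(1024, 2), (1535, 2), (512, 1)])
    def test_floor_rule(self, n, expected):
        assert len(segment_signal(np.zeros(n))) == expected

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            segment_signal(np.zeros(511))


class TestTimeMoments:
    def test_constant_signal(self):
        assert time_moments(np.full(512, 95.0)) == (95.0, 0.0, 0.0, 0.0)

    def test_symmetric_two_level_signal(self):
        x = np.tile([90.0, 100.0], 256)
        m1, m2, m3, m4 = time_moments(x)
        assert m1 == pytest.approx(95.0)
        assert m3 == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_on_random_segment(self, rng):
        x = rng.normal(93, 2, 512)
        np.testing.assert_allclose(time_moments(x), moments_bruteforce(x),
                                   rtol=1e-10)


class TestWelch:
    def test_sinusoid_peak_location(self):
        t = np.arange(4096)
        x = 94 + 2 * np.sin(2 * np.pi * 0.02 * t)
        psd = welch_psd(x)
        peak = psd.frequencies[np.argmax(psd.psd)]
        assert peak == pytest.approx(0.02, abs=psd.resolution)

    def test_resolution_and_grid(self):
        psd = welch_psd(np.random.default_rng(0).normal(size=2048))
        assert len(psd.frequencies) == 513
        assert psd.resolution == pytest.approx(1.0 / 1024)
        assert psd.frequencies[0] == 0 and psd.frequencies[-1] == 0.5

    def test_parseval_within_5_percent(self, rng):
        x = 94 + rng.normal(0, 1.5, 8192)
        psd = welch_psd(x)
        total = psd.psd.sum() * psd.resolution
        assert total == pytest.approx(np.var(x), rel=0.05)

    def test_white_noise_flatness_improves_with_length(self, rng):
        def cv(n):
            psd = welch_psd(rng.normal(size=n))
            return np.std(psd.psd) / np.mean(psd.psd)
        assert cv(32768) < cv(2048)


class TestFreqMoments:
    def test_flat_spectrum(self):
        psd = SpectralEstimate(np.linspace(0, 0.5, 64), np.ones(64))
        m1, m2, m3, m4 = freq_moments(psd)
        assert m1 == pytest.approx(1 / 64)
        assert m2 == pytest.approx(0.0)

    def test_one_hot_spectrum_variance(self):
        n = 64
        p = np.zeros(n)
        p[10] = 7.0
        m1, m2, _, _ = freq_moments(SpectralEstimate(np.linspace(0, 0.5, n), p))
        # normalized one-hot vector: mean 1/n, variance (n-1)/n^2
        assert m1 == pytest.approx(1 / n)
        assert m2 == pytest.approx((n - 1) / n ** 2)

    def test_matches_bruteforce(self, rng):
        p = rng.uniform(0, 1, 129)
        psd = SpectralEstimate(np.linspace(0, 0.5, 129), p)
        np.testing.assert_allclose(freq_moments(psd),
                                   moments_bruteforce(p / p.sum()), rtol=1e-10)

    def test_all_zero_psd_is_error(self):
        with pytest.raises(ValueError, match="empty spectrum"):
            freq_moments(SpectralEstimate(np.linspace(0, 0.5, 8), np.zeros(8)))


class TestMedianFrequencyAndEntropy:
    def test_two_bin_split_takes_first_reaching_half(self):
        f = np.array([0.0, 0.1, 0.2, 0.3])
        p = np.array([0.0, 1.0, 0.0, 1.0])
        assert median_frequency(SpectralEstimate(f, p)) == pytest.approx(0.1)

    def test_single_bin(self):
        f = np.array([0.0, 0.1, 0.2])
        p = np.array([0.0, 0.0, 3.0])
        assert median_frequency(SpectralEstimate(f, p)) == pytest.approx(0.2)

    def test_flat_spectrum_median_near_half_nyquist(self):
        f = np.linspace(0, 0.5, 513)
        mf = median_frequency(SpectralEstimate(f, np.ones(513)))
        assert mf == pytest.approx(0.25, abs=0.002)

    def test_entropy_flat_is_one_onehot_is_zero(self):
        f = np.linspace(0, 0.5, 64)
        assert spectral_entropy(SpectralEstimate(f, np.ones(64))) == pytest.approx(1.0)
        p = np.zeros(64); p[5] = 1
        assert spectral_entropy(SpectralEstimate(f, p)) == pytest.approx(0.0)

    def test_entropy_two_bin_hand_value(self):
        f = np.array([0.0, 0.5])
        se = spectral_entropy(SpectralEstimate(f, np.array([0.9, 0.1])))
        expected = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1)) / np.log(2)
        assert se == pytest.approx(expected)
        assert se == pytest.approx(0.469, abs=0.001)


class TestBandPowers:
    def test_in_band_sinusoid_dominates(self, rng):
        t = np.arange(8192)
        x = 94 + 3 * np.sin(2 * np.pi * 0.02 * t) + rng.normal(0, 0.05, len(t))
        _, pa, pr = band_powers(welch_psd(x))
        assert pr > 0.9
        assert pa > 0

    def test_out_of_band_sinusoid_excluded(self):
        t = np.arange(8192)
        x = 94 + 3 * np.sin(2 * np.pi * 0.25 * t)
        _, _, pr = band_powers(welch_psd(x))
        assert pr < 0.01

    def test_total_power_definition(self, rng):
        psd = welch_psd(rng.normal(94, 1, 4096))
        pt, _, _ = band_powers(psd)
        assert pt == pytest.approx(psd.psd.sum() * psd.resolution)


class TestSampleEntropy:
    def test_constant_signal_is_zero(self):
        with pytest.warns(UserWarning):
            assert sample_entropy(np.full(100, 95.0)) == 0.0

    def test_matches_bruteforce_exactly(self, rng):
        x = rng.normal(94, 2, 100)
        assert sample_entropy(x, m=1, r=0.25) == pytest.approx(
            sampen_bruteforce(x, m=1, r=0.25), abs=1e-12)

    def test_matches_bruteforce_m2_with_external_sd(self, rng):
        x = rng.uniform(85, 99, 120)
        assert sample_entropy(x, m=2, r=0.2, sd=3.0) == pytest.approx(
            sampen_bruteforce(x, m=2, r=0.2, sd=3.0), abs=1e-12)

    def test_noise_more_irregular_than_lowpassed_noise(self, rng):
        x = rng.normal(0, 1, 400)
        smooth = np.convolve(x, np.ones(9) / 9, mode="valid")
        assert sample_entropy(x) > sample_entropy(smooth)


class TestCTM:
    def test_constant_signal_all_points_at_origin(self):
        assert central_tendency_measure(np.full(50, 95.0), rho=0.25) == 1.0

    def test_large_alternating_swings_all_outside(self):
        x = np.tile([90.0, 100.0], 25)
        assert central_tendency_measure(x, rho=1.0) == 0.0

    def test_matches_bruteforce(self, rng):
        x = rng.normal(93, 1.5, 300)
        for rho in (0.1, 0.25, 1.0):
            assert central_tendency_measure(x, rho) == pytest.approx(
                ctm_bruteforce(x, rho))


class TestLZC:
    def test_classic_sequence_hand_parse(self):
        # 0.001.10.100.1000.101 -> six phrases in the exhaustive parsing
        bits = np.array([int(c) for c in "0001101001000101"], bool)
        assert lz76_phrase_count(bits) == 6

    def test_constant_signal_minimal_complexity(self):
        n = 256
        x = np.full(n, 95.0)
        assert lempel_ziv_complexity(x) == pytest.approx(2 * np.log2(n) / n)

    def test_random_sequence_tends_to_one(self, rng):
        x = rng.normal(size=20000)
        assert lempel_ziv_complexity(x) == pytest.approx(1.0, abs=0.15)

    def test_more_random_more_complex(self, rng):
        noise = rng.normal(size=512)
        slow = np.sin(np.arange(512) / 40.0)
        assert lempel_ziv_complexity(noise) > lempel_ziv_complexity(slow)


class TestExtractFeatures:
    def test_all_finite_and_bounded(self, rng):
        x = np.clip(94 + rng.normal(0, 1, 2048), 50, 100)
        fv = extract_features(x)
        arr = fv.to_array()
        assert np.isfinite(arr).all()
        assert 0 <= fv.PR <= 1 and 0 <= fv.SE <= 1 and 0 <= fv.CTM <= 1
        assert fv.M2t >= 0 and 0 <= fv.MF <= 0.5 and fv.LZC >= 0

    def test_deterministic(self, rng):
        x = 94 + rng.normal(0, 1, 1024)
        a = extract_features(x).to_array()
        b = extract_features(x).to_array()
        np.testing.assert_array_equal(a, b)

    def test_adding_constant_changes_only_mean(self, rng):
        x = np.clip(90 + rng.normal(0, 1, 2048), 50, 100)
        a = extract_features(x)
        b = extract_features(x + 5.0)
        assert b.M1t == pytest.approx(a.M1t + 5.0)
        for name in FEATURE_NAMES:
            if name == "M1t":
                continue
            assert getattr(b, name) == pytest.approx(getattr(a, name),
                                                     rel=1e-9, abs=1e-12), name

    def test_periodic_desaturations_raise_band_power(self):
        t = np.arange(4 * 3600)
        quiet = np.full_like(t, 94.0, dtype=float)
        # one trapezoidal dip every 40 s: within the 0.014-0.033 Hz band
        apneic = 94.0 - 4.0 * np.clip(np.sin(2 * np.pi * t / 40.0), 0, 1)
        assert extract_features(apneic).PR > extract_features(quiet + np.sin(t / 500.0)).PR
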