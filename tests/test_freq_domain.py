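import numpy as np
import pytest
from statsmodels.regression.linear_model import burg as sm_burg

from hrvkit import (
    ARConfig,
    EvenlySampledSeries,
    InsufficientDataError,
    ValidationError,
    WelchConfig,
    band_powers,
    burg_coefficients,
    burg_psd,
    frequency_analysis,
    make_ar_process,
    welch_psd,
    PSDEstimate,
)


def white_noise_series(n=256, seed=0, fs=4.0):
    return EvenlySampledSeries(np.random.default_rng(seed).normal(0, 1, n), fs=fs)


class TestWelch:
    def test_zero_signal_gives_zero_psd(self):
        psd = welch_psd(EvenlySampledSeries(np.zeros(512), fs=4.0))
        np.testing.assert_array_equal(psd.power, 0.0)

    def test_segment_count_formula(self):
        psd = welch_psd(EvenlySampledSeries(np.zeros(1024), fs=4.0),
                        WelchConfig(segment_len=256, shift=128))
        assert psd.n_segments_averaged == 7  # floor((1024-256)/128) + 1

    def test_pure_tone_total_power(self):
        t = np.arange(256) / 4.0
        series = EvenlySampledSeries(10.0 * np.sin(2 * np.pi * 0.25 * t), fs=4.0)
        psd = welch_psd(series, WelchConfig(segment_len=256, shift=256, window="rectangular"))
        assert psd.total_power() == pytest.approx(50.0, rel=0.02)  # A^2/2

    def test_parseval_single_rectangular_segment(self):
        for seed in range(20):
            series = white_noise_series(seed=seed)
            psd = welch_psd(series, WelchConfig(segment_len=256, shift=256,
                                                window="rectangular"))
            assert psd.total_power() == pytest.approx(np.var(series.values), rel=0.02)

    def test_average_of_single_segment_estimates(self):
        series = white_noise_series(n=1024, seed=1)
        cfg = WelchConfig(segment_len=256, shift=128, window="hann")
        combined = welch_psd(series, cfg)
        single_cfg = WelchConfig(segment_len=256, shift=256, window="hann")
        singles = []
        for k in range(combined.n_segments_averaged):
            chunk = series.values[k * 128: k * 128 + 256]
            singles.append(welch_psd(EvenlySampledSeries(chunk, fs=4.0), single_cfg).power)
        np.testing.assert_allclose(combined.power, np.mean(singles, axis=0), rtol=1e-9)

    def test_zero_padding_refines_grid_but_not_band_power(self):
        series = white_noise_series(n=1024, seed=2)
        plain = welch_psd(series, WelchConfig(segment_len=256, shift=128))
        padded = welch_psd(series, WelchConfig(segment_len=256, shift=128, padded_len=1024))
        assert len(padded.freqs) > len(plain.freqs)
        bp_plain = band_powers(plain)
        bp_padded = band_powers(padded)
        assert bp_padded.tp == pytest.approx(bp_plain.tp, rel=0.01)

    def test_too_short_series_names_minimum(self):
        with pytest.raises(InsufficientDataError, match="256"):
            welch_psd(EvenlySampledSeries(np.zeros(100), fs=4.0))

    def test_all_named_windows_accepted(self):
        series = white_noise_series(n=512)
        for window in ("hann", "hanning", "hamming", "kaiser", "blackman", "triangular"):
            psd = welch_psd(series, WelchConfig(window=window))
            assert np.all(psd.power >= 0)


class TestBurg:
    def test_white_noise_psd_is_flat_at_analytic_level(self):
        fs = 4.0
        x = np.random.default_rng(3).normal(0, 1.0, 4096)
        series = EvenlySampledSeries(x, fs=fs)
        psd = burg_psd(series, ARConfig(order=4, padded_len=1024))
        interior = (psd.freqs > 0.1) & (psd.freqs < fs / 2 - 0.1)
        expected = 2.0 * np.var(x) / fs
        assert np.mean(psd.power[interior]) == pytest.approx(expected, rel=0.1)

    def test_ar2_coefficient_recovery(self):
        series = make_ar_process([1.2, -0.8], n=8192, seed=7)
        a, sigma2 = burg_coefficients(series.values, 2)
        np.testing.assert_allclose(a, [-1.2, 0.8], atol=0.05)
        assert sigma2 == pytest.approx(1.0, rel=0.1)

    def test_matches_statsmodels_burg(self):
        for seed, order in [(0, 2), (1, 5), (2, 16)]:
            x = make_ar_process([0.5, -0.3], n=2048, seed=seed).values
            a, _ = burg_coefficients(x, order)
            phi_sm, _ = sm_burg(x, order, demean=False)
            np.testing.assert_allclose(a, -phi_sm, rtol=1e-8)

    def test_ar2_spectral_peak_at_closed_form_frequency(self):
        fs = 4.0
        series = make_ar_process([1.2, -0.8], n=8192, seed=7, fs=fs)
        psd = burg_psd(series, ARConfig(order=2, padded_len=4096))
        phi1, phi2 = 1.2, -0.8
        omega0 = np.arccos(-phi1 * (1 - phi2) / (4 * phi2))
        f_expected = omega0 / (2 * np.pi) * fs
        f_peak = psd.freqs[np.argmax(psd.power)]
        assert abs(f_peak - f_expected) <= 2 * (psd.freqs[1] - psd.freqs[0]) + 0.02

    def test_zero_signal_gives_zero_psd(self):
        psd = burg_psd(EvenlySampledSeries(np.zeros(128), fs=4.0))
        np.testing.assert_array_equal(psd.power, 0.0)

    def test_sign_flip_invariance_and_quadratic_scaling(self):
        series = make_ar_process([0.6], n=1024, seed=9)
        base = burg_psd(series, ARConfig(order=4))
        flipped = burg_psd(EvenlySampledSeries(-series.values, fs=series.fs), ARConfig(order=4))
        np.testing.assert_allclose(flipped.power, base.power, rtol=1e-10)
        scaled = burg_psd(EvenlySampledSeries(3.0 * series.values, fs=series.fs), ARConfig(order=4))
        np.testing.assert_allclose(scaled.power, 9.0 * base.power, rtol=1e-10)

    def test_order_at_least_series_length_rejected(self):
        with pytest.raises(ValidationError):
            burg_psd(EvenlySampledSeries(np.ones(10), fs=4.0), ARConfig(order=10))


class TestBandPowers:
    def flat_psd(self, level=100.0, f_max=0.5, n=1001, fs=4.0):
        freqs = np.linspace(0.0, f_max, n)
        return PSDEstimate(freqs, np.full(n, level), method="welch", fs=fs)

    def test_flat_density_band_rectangles(self):
        bp = band_powers(self.flat_psd(level=100.0))
        assert bp.lf == pytest.approx(100.0 * 0.11, rel=1e-9)
        assert bp.hf == pytest.approx(100.0 * 0.25, rel=1e-9)
        assert bp.vlf == pytest.approx(100.0 * 0.04, rel=1e-9)

    def test_contiguous_bands_tile_total_power(self):
        for seed in range(5):
            freqs = np.linspace(0.0, 0.5, 2001)
            power = np.random.default_rng(seed).uniform(0, 50, freqs.size)
            psd = PSDEstimate(freqs, power, method="welch", fs=4.0)
            bp = band_powers(psd)
            assert bp.vlf + bp.lf + bp.hf == pytest.approx(bp.tp, rel=1e-9)
            assert bp.lf_nu + bp.hf_nu == pytest.approx(100.0, rel=1e-9)

    def test_resting_normalized_units_worked_example(self):
        """A PSD whose LF/HF integrals are 1895.67 and 1616.05 ms^2 yields
        normalized units 53.98 / 46.02 and ratio 1.17 (2-decimal rounding)."""
        lf_target, hf_target = 1895.67, 1616.05
        edges = (0.0, 0.04, 0.15, 0.4)
        freqs = np.array([0.0, 0.04, 0.095, 0.15, 0.275, 0.4])
        # triangular bumps: integral = 0.5 * base * height
        lf_height = 2 * lf_target / (0.15 - 0.04)
        hf_height = 2 * hf_target / (0.4 - 0.15)
        power = np.array([0.0, 0.0, lf_height, 0.0, hf_height, 0.0])
        bp = band_powers(PSDEstimate(freqs, power, method="welch", fs=4.0), edges)
        assert bp.lf == pytest.approx(lf_target, rel=1e-12)
        assert bp.hf == pytest.approx(hf_target, rel=1e-12)
        assert round(bp.lf_nu, 2) == 53.98
        assert round(bp.hf_nu, 2) == 46.02
        assert round(bp.lf_hf, 2) == 1.17

    def test_zero_hf_reports_nan_ratio(self):
        freqs = np.linspace(0.0, 0.5, 101)
        power = np.where(freqs < 0.15, 10.0, 0.0)
        bp = band_powers(PSDEstimate(freqs, power, method="welch", fs=4.0))
        assert np.isnan(bp.lf_hf)

    def test_bad_edges_rejected(self):
        with pytest.raises(ValidationError):
            band_powers(self.flat_psd(), (0.0, 0.15, 0.04, 0.4))
        with pytest.raises(ValidationError):
            band_powers(self.flat_psd(f_max=0.3), (0.0, 0.04, 0.15, 0.4))


class TestFrequencyAnalysis:
    def test_two_tone_tachogram_band_structure(self, two_tone_tachogram):
        rri, truth = two_tone_tachogram
        psd, bp = frequency_analysis(rri, method="welch", fs=4.0, detrend_degree=1)
        # spectral peaks at the generating tone frequencies, within one bin
        df = psd.freqs[1] - psd.freqs[0]
        lf_region = (psd.freqs >= 0.04) & (psd.freqs <= 0.15)
        hf_region = (psd.freqs >= 0.15) & (psd.freqs <= 0.4)
        f_lf = psd.freqs[lf_region][np.argmax(psd.power[lf_region])]
        f_hf = psd.freqs[hf_region][np.argmax(psd.power[hf_region])]
        assert abs(f_lf - 0.1) <= df
        assert abs(f_hf - 0.25) <= df
        assert bp.lf > 0.8 * bp.hf
        assert bp.lf > 5 * bp.vlf and bp.hf > 5 * bp.vlf

    def test_single_hf_tone_concentrates_in_hf(self):
        from hrvkit import TachogramSpec, make_tachogram
        rri, _ = make_tachogram(TachogramSpec(
            duration_s=300.0, mean_rri_ms=900.0, tones=((0.25, 20.0, 0.0),), seed=4))
        _, bp = frequency_analysis(rri, method="welch")
        assert bp.hf_nu > 95.0

    def test_constant_tachogram_has_no_power(self):
        from hrvkit import RRiSeries
        _, bp = frequency_analysis(RRiSeries([900.0] * 400), method="welch")
        assert bp.tp < 1e-6

    def test_ar_route_matches_tone_structure(self, two_tone_tachogram):
        rri, _ = two_tone_tachogram
        _, bp = frequency_analysis(rri, method="ar", cfg=ARConfig(order=16, padded_len=1024))
        assert bp.lf > bp.vlf and bp.hf > bp.vlf
        assert bp.lf_nu + bp.hf_nu == pytest.approx(100.0, rel=1e-9)
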