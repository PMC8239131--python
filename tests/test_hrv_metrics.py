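import math

import numpy as np
import pytest

import hrvconcord as hc
from hrvconcord.exceptions import ResolutionWarning, UndefinedMetricError, ValidationError

from conftest import brute_force_rmssd, brute_force_sdnn, pure_tone_series


class TestTimeDomain:
    def test_hand_computed_values(self):
        assert hc.rmssd([800, 800, 800]) == 0.0
        assert hc.rmssd([800, 810, 790]) == pytest.approx(math.sqrt(250), rel=1e-12)
        assert hc.sdnn([800, 800, 800]) == 0.0
        assert hc.sdnn([790, 800, 810]) == pytest.approx(10.0, rel=1e-12)

    def test_too_short_input_is_an_error(self):
        with pytest.raises(UndefinedMetricError):
            hc.rmssd([800])
        with pytest.raises(UndefinedMetricError):
            hc.sdnn([800])

    def test_brute_force_equivalence_on_random_sequences(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            bbis = rng.uniform(400, 1500, rng.integers(2, 80))
            assert hc.rmssd(bbis) == pytest.approx(brute_force_rmssd(list(bbis)), rel=1e-9)
            assert hc.sdnn(bbis) == pytest.approx(brute_force_sdnn(list(bbis)), rel=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        bbis = rng.uniform(700, 900, 300)
        assert hc.rmssd(bbis + 123.0) == pytest.approx(hc.rmssd(bbis), rel=1e-12)
        assert hc.sdnn(bbis + 123.0) == pytest.approx(hc.sdnn(bbis), rel=1e-12)

    def test_iid_gaussian_closed_forms(self):
        # white BBIs: SDNN -> sigma and RMSSD -> sigma * sqrt(2)
        rng = np.random.default_rng(123)
        bbis = 800 + rng.normal(0, 30, 5000)
        assert hc.sdnn(bbis) == pytest.approx(30, rel=0.05)
        assert hc.rmssd(bbis) == pytest.approx(30 * math.sqrt(2), rel=0.05)
        assert 1.3 <= hc.rmssd(bbis) / hc.sdnn(bbis) <= 1.5


class TestTachogram:
    def test_constant_bbis_detrend_to_zero(self, constant_series):
        seg = hc.Segment(constant_series, 0.0, 300000.0)
        t, x = hc.tachogram(seg)
        assert len(x) == 300 * 4
        np.testing.assert_allclose(x, 0.0, atol=1e-9)

    def test_grid_length_matches_duration_times_rate(self, constant_series):
        seg = hc.Segment(constant_series, 0.0, 60000.0)
        t, x = hc.tachogram(seg, resample_hz=4.0)
        assert len(t) == len(x) == 240
        assert t[1] - t[0] == pytest.approx(0.25)

    def test_interpolation_recovers_generating_sinusoid(self):
        # beat times built so that the BBI ending at time t equals
        # 800 + 50 sin(2*pi*0.25*t): the spline must reproduce that curve
        freq, amp = 0.25, 50.0
        times = [0.0]
        while times[-1] < 320000.0:
            t_next = times[-1] + 800.0
            for _ in range(8):  # fixed-point solve for the implicit end time
                t_next = times[-1] + 800.0 + amp * math.sin(2 * math.pi * freq * t_next / 1000.0)
            times.append(t_next)
        series = hc.BeatSeries(np.asarray(times))
        seg = hc.Segment(series, 0.0, 300000.0)
        t, x = hc.tachogram(seg, detrend=False)
        expected = 800.0 + amp * np.sin(2 * math.pi * freq * t)
        interior = (t > 5.0) & (t < 295.0)
        assert np.max(np.abs(x[interior] - expected[interior])) < 2.0

    def test_too_few_beats_is_an_error(self, constant_series):
        seg = hc.Segment(constant_series, 0.0, 2500.0)
        with pytest.raises(UndefinedMetricError):
            hc.tachogram(seg)


class TestBandPower:
    @pytest.mark.parametrize("estimator", ["welch", "lomb_scargle"])
    def test_constant_series_has_no_power(self, constant_series, estimator):
        seg = hc.Segment(constant_series, 0.0, 300000.0)
        lf, hf = hc.band_power(seg, hc.SpectralConfig(estimator=estimator))
        assert lf <= 1e-6 and hf <= 1e-6

    @pytest.mark.parametrize("estimator", ["welch", "lomb_scargle"])
    def test_respiratory_band_tone_lands_in_hf(self, estimator):
        seg = hc.Segment(pure_tone_series(0.25, 50.0), 0.0, 300000.0)
        lf, hf = hc.band_power(seg, hc.SpectralConfig(estimator=estimator))
        assert hf / (lf + hf) >= 0.90

    @pytest.mark.parametrize("estimator", ["welch", "lomb_scargle"])
    def test_baroreflex_band_tone_lands_in_lf(self, estimator):
        seg = hc.Segment(pure_tone_series(0.10, 50.0), 0.0, 300000.0)
        lf, hf = hc.band_power(seg, hc.SpectralConfig(estimator=estimator))
        assert lf / (lf + hf) >= 0.90

    def test_estimators_agree_on_stationary_signals(self):
        cfg = hc.SyntheticConfig(
            duration_h=0.2, jitter_sd_ms=5.0, ectopic_rate_per_h=0, outlier_rate_per_h=0, seed=3
        )
        seg = hc.Segment(hc.generate_recording(cfg), 0.0, 300000.0)
        w_lf, w_hf = hc.band_power(seg, hc.SpectralConfig(estimator="welch"))
        l_lf, l_hf = hc.band_power(seg, hc.SpectralConfig(estimator="lomb_scargle"))
        assert l_lf == pytest.approx(w_lf, rel=0.25)
        assert l_hf == pytest.approx(w_hf, rel=0.25)

    def test_short_window_lf_carries_resolution_warning(self, constant_series):
        with pytest.warns(ResolutionWarning):
            hc.band_power(hc.Segment(constant_series, 0.0, 60000.0))

    def test_mean_shift_leaves_band_power_unchanged(self):
        series = pure_tone_series(0.25, 40.0)
        shifted = hc.BeatSeries.from_bbis(series.bbis + 100.0)
        a = hc.band_power(hc.Segment(series, 0.0, 300000.0))
        b = hc.band_power(hc.Segment(shifted, 0.0, 300000.0))
        assert b[1] == pytest.approx(a[1], rel=0.05)


class TestComputeMetrics:
    def test_constant_segment_is_all_zero(self, constant_series):
        m = hc.compute_metrics(hc.Segment(constant_series, 0.0, 300000.0))
        assert m.rmssd_ms == m.sdnn_ms == 0.0
        assert m.lf_ms2 <= 1e-6 and m.hf_ms2 <= 1e-6
        assert m.n_bbis == 374 and m.duration_s == 300.0

    def test_hf_power_monotone_in_modulation_amplitude(self):
        powers = []
        for amp in (10.0, 30.0, 50.0):
            seg = hc.Segment(pure_tone_series(0.25, amp, jitter_sd_ms=3.0, seed=9), 0.0, 300000.0)
            powers.append(hc.compute_metrics(seg).hf_ms2)
        assert powers[0] < powers[1] < powers[2]

    def test_first_minute_metrics_identical_via_either_path(self, quiet_config):
        series = hc.generate_recording(quiet_config)
        seg5 = hc.Segment(series, 60000.0, 360000.0)
        direct = hc.compute_metrics(hc.Segment(series, 60000.0, 120000.0))
        via_extract = hc.compute_metrics(hc.extract_first_minute(seg5))
        assert direct == via_extract


def test_lf_period_coverage_arithmetic():
    assert hc.lf_period_coverage(60, 0.04) == pytest.approx(2.4)
    assert hc.lf_period_coverage(300, 0.04) == pytest.approx(12.0)
    assert hc.lf_period_coverage(25, 0.04) == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        hc.lf_period_coverage(0, 0.04)
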