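"""QRS detection, tachogram windows, spectral analysis, time-domain indices."""

import numpy as np
import pytest
from scipy import signal as sps

from hrvlit import (
    DEFAULT_BANDS,
    BandDefinition,
    ECGRecord,
    RRWindow,
    band_powers,
    detect_qrs,
    gen_ecg,
    gen_rr_series,
    resample_tachogram,
    rr_from_beats,
    select_segments,
    spectrum,
    subject_features,
    time_domain,
    window_features,
)
from hrvlit.signals import SignalQualityError
from hrvlit.synthetic import EctopicSpec, ModulationSpec


def make_window(intervals_ms, window_s=300.0):
    intervals = np.asarray(intervals_ms, dtype=float)
    times = np.cumsum(intervals)
    return RRWindow(beat_times_ms=times, intervals_ms=intervals,
                    window_s=window_s, start_clock_s=8 * 3600.0)


class TestDetection:
    def test_clean_ecg_recovers_every_beat_within_one_sample(self):
        r_times = 0.5 + 0.8 * np.arange(375)
        ecg, truth = gen_ecg(r_times, noise_sd=0.0)
        beats, template, rejected = detect_qrs(ecg)
        assert len(rejected) == 0
        assert len(beats) == 375
        err_samples = np.abs(beats / 1000.0 - truth.r_time_s.values) * ecg.fs
        assert np.max(err_samples) <= 1.0

    def test_amplitude_outlier_ectopics_are_rejected(self):
        r_times = 0.5 + 0.8 * np.arange(375)
        ecg, truth = gen_ecg(r_times, noise_sd=0.005,
                             ectopic=EctopicSpec(n=5, height_factor=1.8), seed=2)
        _, _, rejected = detect_qrs(ecg)
        ectopic_ms = truth.loc[truth.is_ectopic, "r_time_s"].values * 1000.0
        caught = sum(np.min(np.abs(rejected - t)) < 20.0 for t in ectopic_ms)
        assert caught == 5

    def test_flat_signal_is_quality_error(self):
        ecg = ECGRecord(np.zeros(5000), fs=250.0)
        with pytest.raises(SignalQualityError):
            detect_qrs(ecg)

    def test_short_record_is_quality_error(self):
        ecg = ECGRecord(np.random.default_rng(0).normal(size=500), fs=250.0)
        with pytest.raises(SignalQualityError):
            detect_qrs(ecg)


class TestRRFromBeats:
    def test_interval_arithmetic(self):
        rr = rr_from_beats(np.array([0.0, 800.0, 1600.0]))
        assert np.allclose(rr.intervals_ms, [800.0, 800.0])

    def test_length_contract(self):
        beats = 800.0 * np.arange(375)
        assert rr_from_beats(beats).intervals_ms.size == 374

    def test_interval_spanning_rejected_beat_is_flagged(self):
        beats = np.array([0.0, 800.0, 2400.0, 3200.0])  # gap hides a beat
        rr = rr_from_beats(beats, rejected_times_ms=np.array([1600.0]))
        assert rr.valid.tolist() == [True, False, True]

    def test_too_few_beats(self):
        with pytest.raises(ValueError):
            rr_from_beats(np.array([0.0]))


class TestSegments:
    def test_24h_constant_record_has_96_daytime_windows(self):
        rr = gen_rr_series(86400, 800, [], 0.0, seed=0, start_clock_s=0.0)
        windows = select_segments(rr)
        assert len(windows) == 96  # 8 h of 5-min windows

    def test_night_record_has_no_windows(self):
        rr = gen_rr_series(3600, 800, [], 0.0, seed=0, start_clock_s=22 * 3600.0)
        assert select_segments(rr) == []

    def test_window_with_excess_invalid_intervals_dropped(self):
        rr = gen_rr_series(300, 800, [], 0.0, seed=0, start_clock_s=8 * 3600.0)
        n = rr.intervals_ms.size
        rr.valid[: n // 10] = False  # 10% invalid > 5% default
        assert select_segments(rr) == []


class TestResampling:
    def test_constant_window_resamples_constant(self):
        w = make_window([800.0] * 400)
        series = resample_tachogram(w)
        assert series.size == 1200
        assert np.allclose(series, 800.0)

    def test_slow_sinusoid_amplitude_preserved_within_2pct(self):
        # evenly spaced beats carrying a 0.1 Hz modulation: interpolation at
        # 4 Hz (Nyquist 2 Hz) must preserve the amplitude almost exactly
        times = 800.0 * np.arange(1, 401)
        values = 800.0 + 30.0 * np.sin(2 * np.pi * 0.1 * times / 1000.0)
        w = RRWindow(times, values, window_s=300.0, start_clock_s=0.0)
        series = resample_tachogram(w)
        t = np.arange(series.size) / 4.0
        design = np.column_stack([
            np.sin(2 * np.pi * 0.1 * t), np.cos(2 * np.pi * 0.1 * t),
            np.ones_like(t),
        ])
        coef, *_ = np.linalg.lstsq(design, series, rcond=None)
        amp = np.hypot(coef[0], coef[1])
        assert amp == pytest.approx(30.0, rel=0.02)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            resample_tachogram(make_window([800.0] * 10), fs_resample=0.0)


class TestSpectrum:
    def test_constant_series_has_no_nonzero_frequency_power(self):
        ps = spectrum(np.full(1200, 800.0))
        assert np.allclose(ps.density[1:], 0.0)

    def test_pure_sine_recovers_analytic_power(self):
        t = np.arange(1200) / 4.0
        x = 30.0 * np.sin(2 * np.pi * 0.10 * t)
        ps = spectrum(x)
        near = ps.integrate(0.09, 0.11)
        assert near == pytest.approx(450.0, rel=0.05)

    def test_white_noise_total_power_matches_variance_scale(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.0, 10.0, size=1200)
        ps = spectrum(x)
        assert ps.integrate(0.0, 2.0 + 1e-9) == pytest.approx(100.0, rel=0.10)

    def test_parseval_identity_against_windowed_energy(self):
        """Integral of the corrected density equals the window-weighted
        variance of the series exactly (machine precision)."""
        rng = np.random.default_rng(5)
        x = rng.normal(800.0, 20.0, size=1200)
        ps = spectrum(x)
        w = sps.get_window("hamming", x.size)
        xd = x - x.mean()
        expected = np.sum((w * xd) ** 2) / np.sum(w**2)
        assert ps.integrate(0.0, 2.0 + 1e-9) == pytest.approx(expected, rel=1e-10)

    def test_matches_scipy_periodogram(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 15.0, size=1200)
        ps = spectrum(x)
        freqs, pxx = sps.periodogram(
            x, fs=4.0, window="hamming", detrend="constant", scaling="density"
        )
        assert np.allclose(ps.freqs, freqs)
        assert np.allclose(ps.density, pxx, rtol=1e-9, atol=1e-12)

    def test_nonfinite_series_rejected(self):
        x = np.full(128, 800.0)
        x[5] = np.nan
        with pytest.raises(ValueError):
            spectrum(x)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            spectrum(np.zeros(32))


class TestBandPowers:
    def test_lf_sine_lands_in_lf_band(self):
        t = np.arange(1200) / 4.0
        feats = band_powers(spectrum(800 + 30 * np.sin(2 * np.pi * 0.10 * t)))
        assert feats.lf / feats.tp > 0.9

    def test_hf_sine_dominates_hf(self):
        t = np.arange(1200) / 4.0
        feats = band_powers(spectrum(800 + 30 * np.sin(2 * np.pi * 0.30 * t)))
        assert feats.hf / feats.tp > 0.9
        assert feats.lf_hf < 0.1

    def test_band_midpoint_containment(self):
        t = np.arange(1200) / 4.0
        for band in DEFAULT_BANDS:
            f_mid = 0.5 * (band.f_lo + band.f_hi)
            feats = band_powers(spectrum(800 + 20 * np.sin(2 * np.pi * f_mid * t)))
            assert getattr(feats, band.name) / feats.tp >= 0.9

    def test_zero_spectrum_yields_zero_powers_and_missing_logs(self):
        feats = band_powers(spectrum(np.full(1200, 800.0)))
        assert feats.lf == 0.0 and feats.hf == 0.0 and feats.tp == 0.0
        assert np.isnan(feats.ln_lf) and np.isnan(feats.ln_hf) and np.isnan(feats.lf_hf)

    def test_band_edges_not_double_counted(self):
        ps = spectrum(np.random.default_rng(0).normal(0, 10, 1200))
        parts = sum(ps.integrate(b.f_lo, b.f_hi) for b in DEFAULT_BANDS)
        assert parts == pytest.approx(ps.integrate(0.003, 0.4), rel=1e-12)

    def test_invalid_band_definition(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 0.2, 0.1)


class TestTimeDomain:
    def test_constant_intervals_zero_indices(self):
        assert time_domain(make_window([800.0] * 10)) == (0.0, 0.0)

    def test_alternating_intervals_rmssd(self):
        _, rmssd = time_domain(make_window([790.0, 810.0, 790.0, 810.0]))
        assert rmssd == pytest.approx(20.0)

    def test_two_interval_population_sd(self):
        sdnn, _ = time_domain(make_window([800.0, 900.0]))
        assert sdnn == pytest.approx(50.0)


class TestPipelineProperties:
    def test_ln_transform_preserves_subject_ordering(self):
        rng = np.random.default_rng(2)
        lf = rng.lognormal(5.0, 1.0, size=40)
        ln_lf = np.log(lf)
        assert np.array_equal(np.argsort(lf), np.argsort(ln_lf))

    def test_window_features_deterministic(self):
        rr = gen_rr_series(900, 800, [ModulationSpec(0.1, 25)], 5.0, seed=6)
        a, _ = subject_features(rr)
        b, _ = subject_features(rr)
        assert a.as_dict() == b.as_dict()

    def test_subject_features_on_modulated_record(self):
        rr = gen_rr_series(
            1800, 800,
            [ModulationSpec(0.10, 30.0), ModulationSpec(0.30, 15.0)],
            noise_sd_ms=5.0, seed=1,
        )
        feats, n_windows = subject_features(rr)
        assert n_windows == 6
        assert feats.lf > feats.hf > 0
        assert np.isfinite(feats.ln_lf)
        assert feats.sdnn > 0 and feats.rmssd > 0

    def test_no_window_is_quality_error(self):
        rr = gen_rr_series(600, 800, [], 0.0, seed=0, start_clock_s=0.0)
        with pytest.raises(SignalQualityError):
            subject_features(rr)
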