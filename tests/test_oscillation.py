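"""Oscillation classification, peak calling, IPI/amplitude, ACF, wavelets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import actinwave as aw
from actinwave.oscillation import (
    autocorrelation,
    classify_oscillation,
    detect_peaks,
    interpeak_intervals,
    oscillation_stats,
    peak_amplitudes,
    wavelet_periodogram,
)
from actinwave.traces import NormalizedTrace

from .conftest import as_normalized, brute_force_peaks


def _nt(values, dt=1.0):
    values = np.asarray(values, dtype=float)
    return NormalizedTrace(np.arange(len(values)) * dt, values, dt)


class TestClassifyOscillation:
    def test_pure_sinusoid_called_with_period_within_one_bin(self):
        t = np.arange(301.0)
        call = classify_oscillation(_nt(1 + 0.5 * np.cos(2 * np.pi * t / 25)))
        assert call.is_oscillatory
        f0, df = 1 / 25, 1 / 300
        assert 1 / (f0 + df) <= call.dominant_period <= 1 / (f0 - df)

    def test_constant_trace_negative(self):
        call = classify_oscillation(_nt(np.full(301, 2.0)))
        assert not call.is_oscillatory

    def test_out_of_band_oscillation_negative(self):
        t = np.arange(301.0)
        call = classify_oscillation(_nt(np.cos(2 * np.pi * t / 4)))  # 4 s < band
        assert not call.is_oscillatory

    def test_short_trace_error_names_minimum(self):
        with pytest.raises(aw.InsufficientDataError, match="200"):
            classify_oscillation(_nt(np.zeros(100)))

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        t = np.arange(301.0)
        y = 1 + 0.4 * np.cos(2 * np.pi * t / 33) + rng.normal(0, 0.05, t.size)
        base = classify_oscillation(_nt(y))
        for a, b in [(3.0, -2.0), (0.1, 100.0)]:
            other = classify_oscillation(_nt(a * y + b))
            assert other.is_oscillatory == base.is_oscillatory
            assert other.dominant_period == pytest.approx(base.dominant_period)
            assert other.peak_power_ratio == pytest.approx(base.peak_power_ratio)

    def test_pulse_train_harmonics_do_not_defeat_call(self):
        cfg = aw.TraceConfig(period=32.0, amplitude=5.0, noise_sd=0.5,
                             waveform="pulse")
        nt = as_normalized(aw.make_trace(cfg, 3))
        assert classify_oscillation(nt).is_oscillatory

    def test_two_distinct_periodicities_rejected(self):
        t = np.arange(301.0)
        y = np.cos(2 * np.pi * t / 23) + np.cos(2 * np.pi * t / 61)
        assert not classify_oscillation(_nt(y)).is_oscillatory


class TestDetectPeaks:
    def test_triangle_single_apex(self):
        vals = np.r_[np.arange(15.0), np.arange(13.0, -1.0, -1)]
        pk = detect_peaks(_nt(vals), half_window=5)
        assert list(pk.indices) == [14]

    def test_sinusoid_peak_spacing(self):
        t = np.arange(301.0)
        pk = detect_peaks(_nt(np.cos(2 * np.pi * t / 30)))
        assert abs(len(pk) - 10) <= 1
        assert np.allclose(np.diff(pk.times), 30.0)

    def test_constant_trace_no_peaks(self):
        assert len(detect_peaks(_nt(np.ones(50)))) == 0

    def test_plateau_tie_yields_no_peak(self):
        vals = np.r_[np.zeros(10), [5.0, 5.0], np.zeros(10)]
        assert len(detect_peaks(_nt(vals), half_window=3)) == 0

    def test_half_window_below_frame_interval_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(_nt(np.zeros(20), dt=2.0), half_window=1.0)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        data=st.lists(
            st.integers(min_value=0, max_value=8), min_size=2, max_size=60
        ),
        w=st.integers(min_value=1, max_value=12),
    )
    def test_matches_bruteforce_oracle(self, data, w):
        vals = np.asarray(data, dtype=float)
        pk = detect_peaks(_nt(vals), half_window=float(w))
        assert list(pk.indices) == brute_force_peaks(vals, w)


class TestIpiAndAmplitude:
    def test_hand_arithmetic(self):
        vals = np.zeros(70)
        vals[[10, 34, 58]] = 5.0
        pk = detect_peaks(_nt(vals))
        st_ = interpeak_intervals(pk)
        assert st_.ipi_mean == pytest.approx(24.0)
        assert st_.ipi_sd == pytest.approx(0.0)

    def test_single_peak_empty_ipi(self):
        vals = np.zeros(40)
        vals[20] = 1.0
        st_ = interpeak_intervals(detect_peaks(_nt(vals)))
        assert st_.n_peaks == 1 and np.isnan(st_.ipi_mean)

    def test_pulse_train_ipi_matches_period(self):
        cfg = aw.TraceConfig(period=24.6, frame_interval=0.6, amplitude=4.0,
                             baseline=5.0, background=1.0, noise_sd=0.0)
        nt = aw.normalize_trace(aw.make_trace(cfg, 0), background=1.0)
        st_ = interpeak_intervals(detect_peaks(nt))
        assert abs(st_.ipi_mean - 24.6) <= 0.6

    def test_amplitude_of_noiseless_normalized_pulse(self):
        cfg = aw.TraceConfig(period=25, frame_interval=1.0, amplitude=4.0,
                             baseline=5.0, background=1.0, noise_sd=0.0)
        nt = aw.normalize_trace(aw.make_trace(cfg, 0), background=1.0)
        st_ = peak_amplitudes(nt, detect_peaks(nt))
        assert st_.amp_mean == pytest.approx(1.8, abs=1e-12)

    def test_doubling_amplitude_doubles_excess(self):
        def mean_amp(amp):
            cfg = aw.TraceConfig(period=25, frame_interval=1.0, amplitude=amp,
                                 baseline=5.0, background=1.0, noise_sd=0.0)
            nt = aw.normalize_trace(aw.make_trace(cfg, 0), background=1.0)
            return peak_amplitudes(nt, detect_peaks(nt)).amp_mean
        assert mean_amp(8.0) - 1 == pytest.approx(2 * (mean_amp(4.0) - 1), abs=1e-9)

    def test_constant_trace_no_amplitudes(self):
        nt = _nt(np.ones(60))
        st_ = oscillation_stats(nt, detect_peaks(nt))
        assert st_.n_peaks == 0 and np.isnan(st_.amp_mean)


class TestAutocorrelation:
    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(0)
        res = autocorrelation(_nt(rng.normal(size=200)), max_lag=50)
        assert res.acf[0] == pytest.approx(1.0)

    def test_sinusoid_side_peak_at_period(self):
        t = np.arange(400.0)
        res = autocorrelation(_nt(np.cos(2 * np.pi * t / 40)), max_lag=100)
        assert res.period == pytest.approx(40.0, abs=1.0)

    def test_white_noise_acf_small(self):
        rng = np.random.default_rng(8)
        n = 2000
        res = autocorrelation(_nt(rng.normal(size=n)), max_lag=200)
        frac = np.mean(np.abs(res.acf[1:]) < 3 / np.sqrt(n))
        assert frac >= 0.99


class TestWaveletPeriodogram:
    def test_stationary_sinusoid_ridge(self):
        t = np.arange(400.0)
        wm = wavelet_periodogram(_nt(np.cos(2 * np.pi * t / 30)),
                                 period_range=(5, 100))
        ok = ~np.isnan(wm.ridge)
        assert ok.any()
        scale_step = wm.periods[1] / wm.periods[0]
        assert np.all(wm.ridge[ok] <= 30 * scale_step ** 2)
        assert np.all(wm.ridge[ok] >= 30 / scale_step ** 2)

    def test_period_step_increases_ridge(self):
        # 20 s first half, 60 s second half: ridge trend must step up,
        # mirroring the period lengthening seen after Arp2/3 inhibition
        t1 = np.arange(300.0)
        t2 = np.arange(300.0, 600.0)
        y = np.r_[np.cos(2 * np.pi * t1 / 20), np.cos(2 * np.pi * t2 / 60)]
        wm = wavelet_periodogram(_nt(y), period_range=(10, 100))
        n = len(y)
        first = wm.ridge[n // 6: n // 3]
        second = wm.ridge[2 * n // 3: 5 * n // 6]
        assert np.nanmedian(second) > 1.5 * np.nanmedian(first)

    def test_constant_trace_has_no_ridge(self):
        wm = wavelet_periodogram(_nt(np.ones(300)), period_range=(5, 50))
        assert np.all(np.isnan(wm.ridge))

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            wavelet_periodogram(_nt(np.ones(100)), period_range=(1.0, 500.0))

    def test_coi_masks_edges(self):
        t = np.arange(400.0)
        wm = wavelet_periodogram(_nt(np.cos(2 * np.pi * t / 30)),
                                 period_range=(5, 100))
        assert np.isnan(wm.ridge[0]) and np.isnan(wm.ridge[-1])


class TestOperatingCharacteristics:
    def test_classifier_operating_characteristics(self):
        """Monte-Carlo calibration: sensitivity and specificity >= 95% at the
        shipped default thresholds (SNR 5 pulse trains vs white noise)."""
        n = 100  # the full 200+200 sweep runs in the acceptance suite
        fp = sum(
            classify_oscillation(
                as_normalized(aw.make_trace(
                    aw.TraceConfig(period=0, amplitude=0, noise_sd=1.0), s))
            ).is_oscillatory
            for s in range(n)
        )
        misses = 0
        for s in range(n):
            p = float(np.random.default_rng(1000 + s).uniform(15, 80))
            cfg = aw.TraceConfig(period=p, amplitude=5.0, noise_sd=1.0)
            call = classify_oscillation(as_normalized(aw.make_trace(cfg, s)))
            misses += not call.is_oscillatory
        assert fp / n <= 0.05
        assert misses / n <= 0.05
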