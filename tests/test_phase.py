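"""Cross-correlation lags, cycle-aligned profiles, cohort summaries."""

import numpy as np
import pytest

import actinwave as aw
from actinwave.oscillation import detect_peaks
from actinwave.phase import align_cycles, cohort_lag_summary, crosscorr_lag
from actinwave.traces import NormalizedTrace

from .conftest import as_normalized


def _nt(values, dt=1.0):
    values = np.asarray(values, dtype=float)
    return NormalizedTrace(np.arange(len(values)) * dt, values, dt)


class TestCrosscorrLag:
    def test_self_correlation(self):
        cfg = aw.TraceConfig(noise_sd=0.3)
        nt = as_normalized(aw.make_trace(cfg, 0))
        est = crosscorr_lag(nt, nt, max_lag=10.0)
        assert est.lag == pytest.approx(0.0, abs=1e-9)
        assert est.peak_correlation == pytest.approx(1.0, abs=1e-9)

    def test_constructed_four_frame_shift(self):
        cfg = aw.TraceConfig(frame_interval=0.6, noise_sd=0.0)
        a, b = aw.make_paired_traces(cfg, lag=2.4, seed=0)
        est = crosscorr_lag(as_normalized(a), as_normalized(b), max_lag=10.0,
                            refine=False)
        assert est.lag == pytest.approx(2.4, abs=1e-9)
        assert est.method == "frame"

    def test_antisymmetry(self):
        cfg = aw.TraceConfig(noise_sd=0.5)
        a, b = aw.make_paired_traces(cfg, lag=3.0, seed=5)
        ab = crosscorr_lag(as_normalized(a), as_normalized(b), max_lag=10.0)
        ba = crosscorr_lag(as_normalized(b), as_normalized(a), max_lag=10.0)
        assert ab.lag == pytest.approx(-ba.lag, abs=1e-9)

    def test_flat_trace_rejected(self):
        flat = _nt(np.ones(100))
        wavy = _nt(np.cos(np.arange(100.0)))
        with pytest.raises(aw.CorrelationError):
            crosscorr_lag(flat, wavy, max_lag=5.0)

    def test_mismatched_sampling_rejected(self):
        a = _nt(np.cos(np.arange(100.0)), dt=1.0)
        b = _nt(np.cos(np.arange(100.0)), dt=0.5)
        with pytest.raises(aw.CorrelationError, match="resample"):
            crosscorr_lag(a, b, max_lag=5.0)

    def test_short_overlap_rejected(self):
        a = _nt(np.cos(np.arange(30.0)))
        with pytest.raises(aw.InsufficientDataError):
            crosscorr_lag(a, a, max_lag=10.0)

    def test_parabolic_refinement_resolves_subframe_lag(self):
        # true lag of 1.5 frames: frame-resolution answer is off by half a
        # frame, the refined one much closer
        cfg = aw.TraceConfig(frame_interval=1.0, period=30, noise_sd=0.0,
                             waveform="sinusoid")
        a, b = aw.make_paired_traces(cfg, lag=1.5, seed=0)
        est = crosscorr_lag(as_normalized(a), as_normalized(b), max_lag=10.0)
        assert est.method == "parabolic"
        assert est.lag == pytest.approx(1.5, abs=0.25)


class TestAlignCycles:
    def test_follower_equals_reference(self):
        cfg = aw.TraceConfig(period=30, noise_sd=0.0)
        nt = aw.normalize_trace(aw.make_trace(cfg, 0), background=1.0)
        pk = detect_peaks(nt)
        ref, fol = align_cycles(nt, pk, nt, window=15.0)
        assert np.allclose(ref.mean, fol.mean)
        assert np.allclose(ref.sd, 0.0)
        assert ref.n_cycles >= 2

    def test_reference_profile_peaks_at_zero(self):
        cfg = aw.TraceConfig(period=30, noise_sd=0.0)
        nt = aw.normalize_trace(aw.make_trace(cfg, 0), background=1.0)
        ref, _ = align_cycles(nt, detect_peaks(nt), nt, window=15.0)
        assert ref.rel_times[np.argmax(ref.mean)] == pytest.approx(0.0)

    def test_follower_argmax_at_lag(self):
        cfg = aw.TraceConfig(period=30, frame_interval=1.0, noise_sd=0.0)
        a, b = aw.make_paired_traces(cfg, lag=2.0, seed=0)
        na, nb = as_normalized(a), as_normalized(b)
        ref, fol = align_cycles(na, detect_peaks(na), nb, window=15.0)
        assert fol.rel_times[np.argmax(fol.mean)] == pytest.approx(2.0, abs=1.0)

    def test_two_identical_cycles_sd_zero(self):
        one_cycle = np.r_[np.zeros(5), [1, 3, 1.0], np.zeros(5)]
        vals = np.r_[one_cycle, one_cycle]
        nt = _nt(vals)
        pk = detect_peaks(nt, half_window=4.0)
        ref, _ = align_cycles(nt, pk, nt, window=3.0)
        assert ref.n_cycles == 2
        assert np.allclose(ref.sd, 0.0)

    def test_no_supported_peak_raises(self):
        vals = np.zeros(40)
        vals[1] = 5.0  # peak too close to the edge for a +/-10 s window
        nt = _nt(vals)
        pk = detect_peaks(nt, half_window=3.0)
        with pytest.raises(aw.InsufficientDataError):
            align_cycles(nt, pk, nt, window=10.0)

    def test_agrees_with_crosscorr_sign(self, two_channel_scene):
        cfg, stack, truth = two_channel_scene
        roi = aw.RoiSpec(38, 38, 20)
        bg = aw.RoiSpec(0, 0, 10)
        nts = {}
        for ch in ("lead", "trail"):
            bgval = aw.estimate_background(stack, bg, channel=ch)
            nts[ch] = aw.normalize_trace(
                aw.extract_roi_trace(stack, roi, ch), bgval)
        est = crosscorr_lag(nts["lead"], nts["trail"], max_lag=10.0)
        pk = detect_peaks(nts["lead"])
        _, fol = align_cycles(nts["lead"], pk, nts["trail"], window=12.0)
        argmax_t = fol.rel_times[np.argmax(fol.mean)]
        # positive lag (lead precedes) puts the follower peak at +lag
        assert est.lag > 0
        assert argmax_t == pytest.approx(est.lag, abs=1.0)


class TestCohortSummary:
    def test_two_cell_arithmetic(self):
        s = cohort_lag_summary([2.0, 2.6])
        assert s.mean == pytest.approx(2.3)
        assert s.sd == pytest.approx(0.424, abs=1e-3)
        assert s.n == 2

    def test_single_cell(self):
        s = cohort_lag_summary([1.7])
        assert s.mean == 1.7 and s.sd == 0.0 and s.sem == 0.0 and s.n == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_lag_summary([])

    def test_cohort_recovery_of_true_lag(self):
        # 30 simulated cells with 2.3 s true lead, noisy: the cohort mean
        # must land within 2 SEM of the truth
        cfg = aw.TraceConfig(period=30, frame_interval=0.6, amplitude=5.0,
                             noise_sd=1.0)
        lags = []
        for cell in range(30):
            a, b = aw.make_paired_traces(cfg, lag=2.3, seed=100 + cell)
            lags.append(crosscorr_lag(as_normalized(a), as_normalized(b),
                                      max_lag=10.0))
        s = cohort_lag_summary(lags)
        assert abs(s.mean - 2.3) <= 2 * max(s.sem, 1e-6)

    def test_phase_randomized_surrogates_lose_correlation(self):
        cfg = aw.TraceConfig(period=30, frame_interval=1.0, amplitude=5.0,
                             noise_sd=1.0)
        hits = 0
        for run in range(10):
            a, b = aw.make_paired_traces(cfg, lag=2.0, seed=200 + run)
            na, nb = as_normalized(a), as_normalized(b)
            true_corr = crosscorr_lag(na, nb, max_lag=10.0).peak_correlation
            rng = np.random.default_rng(300 + run)
            null = []
            for _ in range(20):
                spec = np.fft.rfft(nb.values - nb.values.mean())
                phases = rng.uniform(0, 2 * np.pi, spec.size)
                phases[0] = 0.0
                surr = np.fft.irfft(np.abs(spec) * np.exp(1j * phases),
                                    n=len(nb.values))
                ns = _nt(surr, dt=1.0)
                null.append(crosscorr_lag(na, ns, max_lag=10.0).peak_correlation)
            if true_corr > np.quantile(null, 0.95):
                hits += 1
        assert hits >= 9
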