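"""Cross-correlation, spectra, harmonic detection and session metrics."""

import dataclasses
import warnings

import numpy as np
import pytest

from equisync import (AnalysisParams, CorrelationProfile, HarmonicSet,
                      HorseGaitConfig, RiderCouplingConfig, align_pair,
                      cross_correlation, detect_harmonics,
                      generate_horse_walk, generate_rider_response,
                      harmonic_rmse, max_corr_and_lag, session_metrics,
                      welch_psd)
from equisync import errors

from conftest import brute_lagged_pearson, make_signal


class TestCrossCorrelation:
    @pytest.mark.parametrize("method", ["fft", "direct"])
    def test_matches_double_loop_oracle(self, method, rng):
        x = rng.normal(size=1500)
        y = rng.normal(size=1500)
        prof = cross_correlation(make_signal(x), make_signal(y), 1.0,
                                 method=method)
        expect = brute_lagged_pearson(x - x.mean(), y - y.mean(), 100)
        assert np.max(np.abs(prof.r - expect)) < 1e-9

    def test_fft_and_direct_agree(self, rng):
        x, y = rng.normal(size=3000), rng.normal(size=3000)
        a = cross_correlation(make_signal(x), make_signal(y), 2.0, method="fft")
        b = cross_correlation(make_signal(x), make_signal(y), 2.0, method="direct")
        assert a.r == pytest.approx(b.r, abs=1e-12)

    def test_self_correlation_is_one_at_zero_lag(self, rng):
        x = rng.normal(size=2000)
        prof = cross_correlation(make_signal(x), make_signal(x), 1.0)
        assert prof.r[prof.lags == 0.0][0] == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip_gives_minus_one(self, rng):
        x = rng.normal(size=2000)
        sx = make_signal(x)
        prof = cross_correlation(sx, make_signal(-x), 1.0)
        assert prof.r[prof.lags == 0.0][0] == pytest.approx(-1.0, abs=1e-12)

    def test_lag_grid_symmetric_about_zero(self, rng):
        x = rng.normal(size=2000)
        prof = cross_correlation(make_signal(x), make_signal(x), 1.5)
        assert prof.lags[0] == -prof.lags[-1]
        assert 0.0 in prof.lags
        assert np.allclose(np.diff(prof.lags), 0.01)

    def test_bounded_on_constant_segment_signals(self, rng):
        # adversarial: long constant runs give zero-variance overlaps
        x = np.r_[np.zeros(800), rng.normal(size=400), np.zeros(800)]
        y = np.r_[np.ones(1000) * 5.0, rng.normal(size=1000)]
        prof = cross_correlation(make_signal(x), make_signal(y), 2.0)
        assert np.all(np.isfinite(prof.r))
        assert np.all(np.abs(prof.r) <= 1.0)

    def test_rate_mismatch_rejected(self, rng):
        a = make_signal(rng.normal(size=2000), rate=100.0)
        b = make_signal(rng.normal(size=1000), rate=50.0)
        with pytest.raises(errors.ParameterError, match="rate"):
            cross_correlation(a, b, 1.0)

    def test_requires_baseline_removed(self, rng):
        a = make_signal(rng.normal(size=2000))
        b = make_signal(rng.normal(size=2000), demean=False)
        with pytest.raises(errors.ContractError):
            cross_correlation(a, b, 1.0)

    def test_overlap_shorter_than_10s_rejected(self, rng):
        a = make_signal(rng.normal(size=1100))  # 11 s at 100 Hz
        with pytest.raises(errors.ParameterError, match="overlap"):
            cross_correlation(a, a, 2.0)


class TestMaxCorrAndLag:
    def test_recovers_constructed_delay(self):
        # rider-lags-horse sign convention: delayed copy -> positive lag
        t = np.arange(6000) / 100.0
        ref = make_signal(np.sin(2 * np.pi * 1.5 * t))
        delayed = make_signal(np.sin(2 * np.pi * 1.5 * (t - 0.20)))
        mc, lag = max_corr_and_lag(cross_correlation(ref, delayed, 0.3))
        assert mc >= 0.99
        assert lag == pytest.approx(0.20, abs=0.01)

    def test_identical_signals_give_one_at_zero(self, rng):
        x = make_signal(rng.normal(size=3000))
        mc, lag = max_corr_and_lag(cross_correlation(x, x, 1.0))
        assert (mc, lag) == (pytest.approx(1.0, abs=1e-12), 0.0)

    def test_exact_tie_broken_by_smallest_abs_lag(self):
        prof = CorrelationProfile(lags=np.array([-0.5, 0.0, 0.5]),
                                  r=np.array([1.0, 1.0, 1.0]))
        assert max_corr_and_lag(prof) == (1.0, 0.0)

    def test_exact_tie_at_equal_abs_lag_prefers_negative(self):
        prof = CorrelationProfile(lags=np.array([-0.1, 0.1]),
                                  r=np.array([0.8, 0.8]))
        assert max_corr_and_lag(prof) == (0.8, -0.1)

    def test_periodic_signal_tie_resolves_to_zero(self):
        # a pure 1.5 Hz sine repeats every 2/3 s; the zero-lag peak wins
        t = np.arange(6000) / 100.0
        s = make_signal(np.sin(2 * np.pi * 1.5 * t))
        _, lag = max_corr_and_lag(cross_correlation(s, s, 1.0))
        assert lag == 0.0

    def test_empty_profile_rejected(self):
        prof = CorrelationProfile(lags=np.array([]), r=np.array([]))
        with pytest.raises(errors.ParameterError):
            max_corr_and_lag(prof)


class TestWelchPsd:
    def test_zero_signal_gives_zero_psd(self):
        spec = welch_psd(make_signal(np.zeros(6000), demean=False), 20.0, 0.5)
        assert np.all(spec.psd == 0)

    def test_parseval_total_power_matches_variance(self, rng):
        from scipy.signal import butter, sosfiltfilt
        sos = butter(4, 20.0, fs=100.0, output="sos")
        v = sosfiltfilt(sos, rng.normal(size=60000))
        v /= v.std()
        spec = welch_psd(make_signal(v), 20.0, 0.5)
        total = np.trapezoid(spec.psd, spec.freqs)
        assert total == pytest.approx(np.var(v), rel=0.10)

    def test_pure_tone_peak_location_and_resolution(self):
        t = np.arange(6000) / 100.0
        spec = welch_psd(make_signal(np.sin(2 * np.pi * 2.0 * t)), 20.0, 0.5)
        assert spec.resolution == pytest.approx(0.05)
        assert spec.freqs[np.argmax(spec.psd)] == pytest.approx(2.0, abs=0.05)

    def test_too_short_signal_rejected(self):
        with pytest.raises(errors.ParameterError, match="short"):
            welch_psd(make_signal(np.zeros(1500), demean=False), 20.0, 0.5)

    def test_invalid_overlap_rejected(self):
        with pytest.raises(errors.ParameterError):
            welch_psd(make_signal(np.zeros(6000), demean=False), 20.0, 1.0)


def _oracle_local_maxima(psd):
    """Exhaustive scan for interior local maxima (independent oracle)."""
    return [i for i in range(1, len(psd) - 1)
            if psd[i] > psd[i - 1] and psd[i] >= psd[i + 1]]


class TestDetectHarmonics:
    @staticmethod
    def _spectrum(freqs_amps, seconds=120):
        t = np.arange(seconds * 100) / 100.0
        v = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
        return welch_psd(make_signal(v), 20.0, 0.5)

    def test_walk_harmonic_stack_recovered(self):
        spec = self._spectrum([(1.5, 1.0), (3.0, 0.5), (4.5, 0.25)])
        hs = detect_harmonics(spec, (1.0, 6.0), 3)
        assert hs.peak_freqs == pytest.approx([1.5, 3.0, 4.5], abs=spec.resolution)
        assert not hs.missing.any()

    def test_pure_tone_fundamental(self):
        spec = self._spectrum([(2.0, 1.0)])
        hs = detect_harmonics(spec, (1.0, 6.0), 1)
        assert hs.fundamental == pytest.approx(2.0, abs=0.05)

    def test_missing_second_harmonic_flagged(self):
        spec = self._spectrum([(1.5, 1.0), (4.5, 0.5)])
        hs = detect_harmonics(spec, (1.0, 6.0), 3)
        assert list(hs.missing) == [False, True, False]
        assert np.isnan(hs.peak_freqs[1])
        assert hs.peak_freqs[[0, 2]] == pytest.approx([1.5, 4.5], abs=0.05)
        # detected peaks agree with an exhaustive local-maximum scan
        oracle = [spec.freqs[i] for i in _oracle_local_maxima(spec.psd)
                  if spec.psd[i] > 1e-3 * spec.psd.max()]
        for f in hs.peak_freqs[[0, 2]]:
            assert any(abs(f - of) < 1e-9 for of in oracle)

    def test_dominant_second_harmonic_not_mistaken_for_fundamental(self):
        # when the 2x peak is strongest the weaker 1x peak still anchors
        # the fundamental unless it is truly dominant
        spec = self._spectrum([(1.5, 1.0), (3.0, 0.9)])
        hs = detect_harmonics(spec, (1.0, 6.0), 2)
        assert hs.fundamental == pytest.approx(1.5, abs=0.05)

    def test_no_peak_in_band_raises(self):
        spec = welch_psd(make_signal(np.zeros(6000), demean=False), 20.0, 0.5)
        with pytest.raises(errors.NoPeakError):
            detect_harmonics(spec, (1.0, 6.0), 3)

    def test_band_below_resolution_rejected(self):
        spec = self._spectrum([(2.0, 1.0)])
        with pytest.raises(errors.ParameterError):
            detect_harmonics(spec, (0.01, 6.0), 1)


def _harmonic_set(freqs, powers=None, missing=None):
    freqs = np.asarray(freqs, float)
    k = len(freqs)
    present = freqs[~np.isnan(freqs)]
    return HarmonicSet(
        fundamental=float(present[0]) if present.size else 1.0,
        peak_freqs=freqs,
        peak_powers=np.asarray(powers if powers is not None else np.ones(k), float),
        missing=np.asarray(missing if missing is not None else np.isnan(freqs)),
        K=k)


class TestHarmonicRmse:
    def test_identical_sets_give_zero(self):
        a = _harmonic_set([1.5, 3.0, 4.5])
        assert harmonic_rmse(a, a) == 0.0

    def test_closed_form_value(self):
        a = _harmonic_set([1.5, 3.0, 4.5])
        b = _harmonic_set([1.6, 3.1, 4.4])
        assert harmonic_rmse(a, b) == pytest.approx(np.sqrt(0.03 / 3), abs=1e-12)

    def test_random_perturbations_match_formula(self, rng):
        base = np.array([1.5, 3.0, 4.5])
        delta = rng.normal(0, 0.1, 3)
        got = harmonic_rmse(_harmonic_set(base), _harmonic_set(base + delta))
        assert got == pytest.approx(np.sqrt(np.mean(delta ** 2)), abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        a = _harmonic_set([1.4, 3.1, 4.6])
        b = _harmonic_set([1.6, 2.9, 4.4])
        assert harmonic_rmse(a, b) == harmonic_rmse(b, a)

    @pytest.mark.parametrize("c", [0.5, 2.0, 60.0])
    def test_scale_covariance(self, c):
        a = _harmonic_set([1.5, 3.0, 4.5])
        b = _harmonic_set([1.6, 3.1, 4.4])
        ac = _harmonic_set(a.peak_freqs * c)
        bc = _harmonic_set(b.peak_freqs * c)
        assert harmonic_rmse(ac, bc) == pytest.approx(
            c * harmonic_rmse(a, b), rel=1e-12)

    def test_missing_pairs_dropped_with_warning(self):
        a = _harmonic_set([1.5, np.nan, 4.5])
        b = _harmonic_set([1.6, 3.0, 4.4])
        with pytest.warns(UserWarning, match="missing"):
            got = harmonic_rmse(a, b)
        assert got == pytest.approx(np.sqrt((0.1 ** 2 + 0.1 ** 2) / 2), abs=1e-9)

    def test_all_missing_is_undefined(self):
        a = _harmonic_set([np.nan, np.nan])
        b = _harmonic_set([1.0, 2.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(errors.UndefinedMetricError):
                harmonic_rmse(a, b)

    def test_power_mode_uses_peak_powers(self):
        a = _harmonic_set([1.5, 3.0], powers=[2.0, 1.0])
        b = _harmonic_set([1.5, 3.0], powers=[1.0, 1.0])
        assert harmonic_rmse(a, b, mode="power") == pytest.approx(
            np.sqrt(0.5), abs=1e-12)


def _synthetic_pair(coupling, lag, noise_sd, duration=90.0, seed=0,
                    sway=0.2):
    horse = generate_horse_walk(HorseGaitConfig(duration_s=duration), seed)
    rider = generate_rider_response(
        horse, RiderCouplingConfig(coupling_gain=coupling, lag_s=lag,
                                   rider_noise_sd=noise_sd,
                                   intrinsic_sway_amp=sway), seed + 1)
    return align_pair(horse, rider, participant_id="P", session_index=1)


class TestSessionMetrics:
    def test_injected_lag_and_coupling_recovered(self):
        # 20 dB SNR: noise sd = coupled signal rms / 10
        sig_rms = np.sqrt(sum(a ** 2 / 2 for a in (1.0, 0.5, 0.25)))
        res = session_metrics(_synthetic_pair(0.9, 0.30, 0.9 * sig_rms / 10))
        assert res.metrics.lag_at_max == pytest.approx(0.30, abs=0.02)
        assert res.metrics.max_corr > 0.6

    def test_rider_identical_to_horse_degenerates(self):
        horse = generate_horse_walk(HorseGaitConfig(duration_s=90.0), 3)
        rider = dataclasses.replace(horse, placement="rider_head")
        pair = align_pair(horse, rider, participant_id="P", session_index=1)
        m = session_metrics(pair).metrics
        assert m.max_corr == pytest.approx(1.0, abs=1e-9)
        assert m.lag_at_max == 0.0
        assert m.rmse_freq == 0.0

    def test_uncoupled_rider_has_near_zero_correlation(self):
        # null bound for 600 s at 100 Hz
        res = session_metrics(_synthetic_pair(0.0, 0.0, 1.0, duration=620.0))
        assert abs(res.metrics.max_corr) < 0.1

    def test_errors_annotated_with_participant_and_session(self):
        pair = _synthetic_pair(0.8, 0.3, 0.1)
        bad = AnalysisParams(welch_window_s=60.0)  # longer than half the session
        with pytest.raises(errors.ParameterError, match="participant 'P' session 1"):
            session_metrics(pair, bad)

    def test_intermediates_exposed(self):
        res = session_metrics(_synthetic_pair(0.8, 0.3, 0.1))
        assert res.profile.r.size == 401  # 2 s max lag at 100 Hz
        assert res.horse_spectrum.freqs[-1] == pytest.approx(50.0)
        assert res.horse_harmonics.K == 3
        assert res.horse_signal.n == res.rider_signal.n
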