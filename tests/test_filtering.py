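"""Filter design, zero-phase application, rate detection, refined movies."""

import numpy as np
import pytest
from scipy import signal as sps

from eitsep.filtering import (BandSpec, RateEstimate, apply_zero_phase,
                              design_bandpass, estimate_rates,
                              frequency_response, refine_movies, refined_bands,
                              rough_split, ROUGH_CARDIAC_BAND, ROUGH_RESP_BAND,
                              NYQUIST_CAP)
from eitsep.synth import SimulationParams, simulate_recording


def _sine(freq, fs, duration, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t + phase)


def _peak_lag(x, y):
    """Lag of maximal cross-correlation between input and output."""
    x = x - x.mean()
    y = y - y.mean()
    c = sps.correlate(y, x, mode="full")
    return int(np.argmax(c)) - (len(x) - 1)


class TestDesign:
    def test_rough_bands_match_the_bpm_cutoffs(self):
        assert ROUGH_RESP_BAND == (pytest.approx(2 / 60), pytest.approx(40 / 60))
        assert ROUGH_CARDIAC_BAND == (pytest.approx(40 / 60), pytest.approx(400 / 60))
        # at 44 Hz the 400 bpm edge is already below 0.95 * Nyquist
        assert min(400 / 60, NYQUIST_CAP * 22.0) == pytest.approx(400 / 60)

    def test_linear_phase_symmetric_odd_length(self):
        taps = design_bandpass(BandSpec(0.6, 3.0), 44.0)
        assert taps.size % 2 == 1
        np.testing.assert_allclose(taps, taps[::-1], atol=1e-15)

    def test_dc_is_rejected(self):
        taps = design_bandpass(BandSpec(0.6, 3.0), 44.0)
        out = apply_zero_phase(np.ones(10 * taps.size), taps)
        assert np.abs(out).max() < 0.01

    def test_stopband_attenuation_from_frequency_response(self):
        band = BandSpec(0.6, 3.0)
        taps = design_bandpass(band, 44.0)
        f, h = frequency_response(taps, 44.0)
        assert 20 * np.log10(h[f <= 0.5 * band.low].max()) <= -40
        assert 20 * np.log10(h[f >= 1.5 * band.high].max()) <= -40

    def test_band_beyond_nyquist_is_an_error(self):
        with pytest.raises(ValueError, match="Nyquist"):
            design_bandpass(BandSpec(1.0, 30.0), 44.0)


class TestZeroPhase:
    @pytest.mark.parametrize("freq", [0.8, 1.2, 2.0, 2.8])
    def test_passband_amplitude_preserved_and_zero_lag(self, freq):
        fs = 44.0
        taps = design_bandpass(BandSpec(0.6, 3.0), fs)
        x = _sine(freq, fs, 120)
        y = apply_zero_phase(x, taps)
        core = slice(len(x) // 4, -len(x) // 4)
        amp = (y[core].max() - y[core].min()) / 2
        assert amp == pytest.approx(1.0, abs=0.02)
        assert _peak_lag(x[core], y[core]) == 0

    def test_deep_stopband_attenuation_measured_on_a_sinusoid(self):
        fs = 44.0
        band = BandSpec(0.6, 3.0)
        taps = design_bandpass(band, fs)
        x = _sine(0.25 * band.low, fs, 300)
        y = apply_zero_phase(x, taps)
        core = slice(len(x) // 4, -len(x) // 4)
        att_db = 20 * np.log10(np.abs(y[core]).max())
        assert att_db <= -40  # forward-backward doubles the design attenuation

    def test_linearity(self):
        rng = np.random.default_rng(0)
        taps = design_bandpass(BandSpec(0.6, 3.0), 44.0)
        a = rng.normal(size=4000)
        b = rng.normal(size=4000)
        lhs = apply_zero_phase(a + b, taps)
        rhs = apply_zero_phase(a, taps) + apply_zero_phase(b, taps)
        np.testing.assert_allclose(lhs, rhs, rtol=0, atol=1e-9 * np.abs(lhs).max())

    def test_short_signal_is_rejected_with_the_required_length(self):
        taps = design_bandpass(BandSpec(0.6, 3.0), 44.0)
        with pytest.raises(ValueError, match=str(3 * taps.size)):
            apply_zero_phase(np.zeros(3 * taps.size), taps)

    def test_band_split_energy_conservation(self):
        # a respiratory-band plus a cardiac-band sinusoid: each refined output
        # carries its own component's power within 5%
        fs, f_rr, f_hr = 44.0, 0.25, 1.2
        x = _sine(f_rr, fs, 320) + 0.1 * _sine(f_hr, fs, 320)
        resp_taps = design_bandpass(BandSpec(0.5 * f_rr, 2.5 * f_rr), fs)
        card_taps = design_bandpass(BandSpec(0.5 * f_hr, 2.5 * f_hr), fs)
        core = slice(len(x) // 4, -len(x) // 4)
        p_resp = apply_zero_phase(x, resp_taps)[core].var()
        p_card = apply_zero_phase(x, card_taps)[core].var()
        assert p_resp == pytest.approx(0.5, rel=0.05)
        assert p_card == pytest.approx(0.5 * 0.1**2, rel=0.05)


class TestRoughSplitAndRates:
    def test_lung_region_resp_signal_is_dominated_by_f_rr(self, default_recording):
        p, movie, _, truth = default_recording
        resp, cardiac = rough_split(movie, truth.geometry.lung_mask)
        f, pxx = sps.periodogram(resp, fs=p.fs, detrend="linear",
                                 nfft=4 * resp.size)
        assert abs(f[np.argmax(pxx)] - truth.true_f_RR) <= p.fs / resp.size

    def test_empty_region_is_an_error(self, default_recording):
        _, movie, _, _ = default_recording
        with pytest.raises(ValueError, match="empty region"):
            rough_split(movie, np.zeros(movie.grid_shape, dtype=bool))

    def test_rate_estimates_within_one_bin(self, default_recording):
        p, movie, _, truth = default_recording
        resp, cardiac = rough_split(movie, truth.geometry.lung_mask)
        rates = estimate_rates(resp, cardiac, p.fs)
        bin_hz = p.fs / resp.size
        assert abs(rates.f_RR - truth.true_f_RR) <= bin_hz
        assert abs(rates.f_HR - truth.true_f_HR) <= bin_hz
        assert not rates.harmonic_conflict

    def test_exact_harmonic_sets_the_conflict_flag(self):
        p = SimulationParams(seed=8, f_RR=0.3, f_HR=1.2, rate_jitter_cv=0.0,
                             breathing_duration=40.0)
        movie, _, truth = simulate_recording(p)
        resp, cardiac = rough_split(movie, truth.geometry.lung_mask)
        rates = estimate_rates(resp, cardiac, p.fs)
        assert rates.harmonic_conflict

    def test_pure_noise_raises_instead_of_guessing(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(size=2000)
        with pytest.raises(ValueError, match="band"):
            estimate_rates(noise, noise, 44.0)

    def test_noise_region_has_no_peak_above_the_detection_floor(self, default_recording):
        from eitsep.filtering import PEAK_TO_MEDIAN_FLOOR
        p, movie, _, truth = default_recording
        corner = np.zeros(movie.grid_shape, dtype=bool)
        corner[truth.geometry.background_mask] = True
        resp, cardiac = rough_split(movie, corner)
        for sig, band in ((resp, BandSpec(*ROUGH_RESP_BAND)),
                          (cardiac, BandSpec(40 / 60, 400 / 60))):
            f, pxx = sps.periodogram(sig, fs=p.fs, detrend="linear",
                                     nfft=4 * sig.size)
            sel = (f >= band.low) & (f <= band.high)
            assert pxx[sel].max() < PEAK_TO_MEDIAN_FLOOR * np.median(pxx[sel])


class TestRefineMovies:
    def test_refined_bands_cap_resp_edge_below_cardiac(self):
        rates = RateEstimate(f_RR=0.3, f_HR=1.5, resp_peak_power=1,
                             cardiac_peak_power=1)
        resp, cardiac, strict = refined_bands(rates, 44.0)
        assert resp.high == pytest.approx(0.9 * 0.5 * 1.5)  # capped, 5:1 ratio
        assert cardiac.low == pytest.approx(0.75)
        assert strict.low == pytest.approx(1.2) and strict.high == pytest.approx(1.8)

    def test_band_separation_of_the_refined_movies(self, clean_recording):
        p, movie, _, truth = clean_recording
        rates = RateEstimate(f_RR=p.f_RR, f_HR=p.f_HR, resp_peak_power=1,
                             cardiac_peak_power=1)
        resp_m, cardiac_m, _ = refine_movies(movie, rates)
        lung = truth.geometry.lung_mask
        seg = movie.segment("breathing")
        core = slice(seg.start + int(4 * p.fs), seg.end - int(4 * p.fs))

        def band_power(trace, lo, hi):
            f, pxx = sps.periodogram(trace, fs=p.fs, detrend="linear")
            return pxx[(f >= lo) & (f <= hi)].sum()

        resp_trace = resp_m.mean_trace(lung)[core]
        card_trace = cardiac_m.mean_trace(lung)[core]
        resp_band = (0.5 * p.f_RR, 2.5 * p.f_RR)
        card_band = (0.5 * p.f_HR, 2.5 * p.f_HR)
        assert band_power(resp_trace, *card_band) < 0.05 * band_power(resp_trace, *resp_band)
        assert band_power(card_trace, *resp_band) < 0.05 * band_power(card_trace, *card_band)

    def test_strict_band_suppresses_the_harmonics(self, clean_recording):
        p, movie, _, truth = clean_recording
        rates = RateEstimate(f_RR=p.f_RR, f_HR=p.f_HR, resp_peak_power=1,
                             cardiac_peak_power=1)
        _, _, strict_m = refine_movies(movie, rates)
        trace = strict_m.mean_trace(truth.geometry.lung_mask)
        seg = movie.segment("breathing")
        trace = trace[seg.start + int(4 * p.fs):seg.end - int(4 * p.fs)]
        f, pxx = sps.periodogram(trace, fs=p.fs, detrend="linear",
                                 nfft=4 * trace.size)

        def peak_near(freq):
            sel = np.abs(f - freq) < 0.1
            return pxx[sel].max()

        assert peak_near(2 * p.f_HR) <= 1e-2 * peak_near(p.f_HR)  # >= 20 dB down

    def test_unresolved_conflict_demands_manual_override(self, small_recording):
        _, movie, _, _ = small_recording
        rates = RateEstimate(f_RR=0.3, f_HR=1.2, resp_peak_power=1,
                             cardiac_peak_power=1, harmonic_conflict=True,
                             conflict_resolution="unresolved")
        with pytest.raises(ValueError, match="override"):
            refine_movies(movie, rates)
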