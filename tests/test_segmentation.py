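"""Reference region, phase mapping, heart/lung masks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eitsep.io import PixelMovie, Segment
from eitsep.pipeline import process_recording
from eitsep.segmentation import (PhaseMap, RegionMask, compute_phase_map, dice,
                                 find_reference_region, heart_mask, lung_mask,
                                 mask_to_rle, threshold_phase)
from eitsep.synth import SimulationParams, make_geometry, simulate_recording


def _movie_from_traces(traces, fs=44.0):
    """(n, H, W) movie from a {(r, c): trace} dict on a small grid."""
    n = len(next(iter(traces.values())))
    shape = (max(r for r, _ in traces) + 1, max(c for _, c in traces) + 1)
    data = np.zeros((n,) + shape)
    for (r, c), tr in traces.items():
        data[:, r, c] = tr
    return PixelMovie(data, fs, segments=[Segment("breathing", 0, n)])


class TestReferenceRegion:
    def test_single_active_pixel_yields_the_4_connected_cross(self):
        n = 400
        data = np.zeros((n, 16, 16))
        data[:, 10, 10] = np.sin(np.arange(n))
        movie = PixelMovie(data, 44.0)
        ref = find_reference_region(movie)
        expected = {(10, 10), (9, 10), (11, 10), (10, 9), (10, 11)}
        assert set(map(tuple, np.argwhere(ref.mask))) == expected

    def test_corner_argmax_clips_to_the_grid(self):
        n = 400
        data = np.zeros((n, 16, 16))
        data[:, 0, 0] = np.sin(np.arange(n))
        ref = find_reference_region(PixelMovie(data, 44.0))
        assert set(map(tuple, np.argwhere(ref.mask))) == {(0, 0), (1, 0), (0, 1)}

    def test_all_zero_movie_is_an_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            find_reference_region(PixelMovie(np.zeros((300, 8, 8)), 44.0))

    def test_reference_lands_inside_the_true_lung(self, processed_default,
                                                  default_recording):
        # the respiratory-band argmax pixel must be lung tissue
        _, movie, _, truth = default_recording
        from eitsep.filtering import RateEstimate, refine_movies
        p = default_recording[0]
        rates = RateEstimate(f_RR=p.f_RR, f_HR=p.f_HR, resp_peak_power=1,
                             cardiac_peak_power=1)
        resp_m, _, _ = refine_movies(movie, rates)
        ref = find_reference_region(resp_m)
        assert (ref.mask & truth.geometry.lung_mask).sum() >= 3


class TestPhaseMap:
    def _delay_movie(self, delays_deg, f=1.1, fs=44.0, duration=30.0):
        t = np.arange(int(duration * fs)) / fs
        traces = {(0, 0): np.sin(2 * np.pi * f * t)}
        for i, d in enumerate(delays_deg):
            r, c = divmod(i + 1, 8)
            traces[(r, c)] = np.sin(2 * np.pi * f * (t - d / 360.0 / f))
        return _movie_from_traces(traces, fs)

    def test_identical_trace_gives_zero_phase_and_unit_correlation(self):
        movie = self._delay_movie([0.0])
        ref = RegionMask(np.zeros(movie.grid_shape, dtype=bool), "reference")
        ref.mask[0, 0] = True
        pm = compute_phase_map(movie, ref, f_HR=1.1)
        assert pm.phase[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert pm.correlation[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_sign_flipped_trace_maps_to_180_degrees(self):
        movie = self._delay_movie([180.0])
        ref = RegionMask(np.zeros(movie.grid_shape, dtype=bool), "reference")
        ref.mask[0, 0] = True
        pm = compute_phase_map(movie, ref, f_HR=1.1)
        assert abs(pm.phase[0, 1]) == pytest.approx(180.0, abs=360 * 1.1 / 44)

    def test_165_degree_delay_recovered_within_lag_quantization(self):
        movie = self._delay_movie([165.0])
        ref = RegionMask(np.zeros(movie.grid_shape, dtype=bool), "reference")
        ref.mask[0, 0] = True
        pm = compute_phase_map(movie, ref, f_HR=1.1)
        assert pm.phase[0, 1] == pytest.approx(165.0, abs=360 * 1.1 / 44)

    def test_rate_too_high_for_the_frame_rate_is_an_error(self):
        movie = self._delay_movie([0.0])
        ref = RegionMask(np.zeros(movie.grid_shape, dtype=bool), "reference")
        ref.mask[0, 0] = True
        with pytest.raises(ValueError, match="period"):
            compute_phase_map(movie, ref, f_HR=15.0)


class TestHeartMask:
    def _phase_map(self, phase, valid=None):
        phase = np.asarray(phase, dtype=float)
        valid = np.ones_like(phase, dtype=bool) if valid is None else valid
        return PhaseMap(phase=phase, correlation=np.ones_like(phase), valid=valid)

    def test_all_zero_phase_gives_an_empty_mask(self):
        hm = heart_mask(self._phase_map(np.zeros((12, 12))))
        assert hm.n_pixels == 0

    def test_isolated_suprathreshold_pixel_is_opened_away(self):
        phase = np.zeros((12, 12))
        phase[5, 5] = 170.0
        hm = heart_mask(self._phase_map(phase))
        assert hm.n_pixels == 0

    def test_compact_shifted_blob_survives_cleanup(self):
        phase = np.zeros((12, 12))
        phase[3:7, 3:7] = 160.0
        phase[4, 4] = 0.0  # hole: closing should fill it
        hm = heart_mask(self._phase_map(phase))
        assert hm.mask[4, 4]
        assert hm.n_pixels >= 12  # 4x4 blob survives a 3x3-cross opening reduced

    def test_largest_component_is_kept(self):
        phase = np.zeros((16, 16))
        phase[2:8, 2:8] = 160.0
        phase[12:14, 12:14] = 160.0
        hm = heart_mask(self._phase_map(phase))
        assert hm.mask[4, 4] and not hm.mask[12, 12]

    @given(st.integers(10, 80), st.integers(0, 70))
    def test_raising_the_threshold_never_grows_the_raw_mask(self, t, dt):
        rng = np.random.default_rng(0)
        pm = self._phase_map(rng.uniform(-180, 180, size=(16, 16)))
        lo = threshold_phase(pm, t)
        hi = threshold_phase(pm, t + dt)
        assert not (hi & ~lo).any()

    def test_recovers_the_true_heart_region(self, processed_default,
                                            default_recording):
        truth = default_recording[3]
        assert dice(processed_default.heart.mask,
                    truth.geometry.heart_mask) >= 0.8


class TestLungMask:
    def test_recovers_the_true_lung_region(self, processed_default,
                                           default_recording):
        truth = default_recording[3]
        assert dice(processed_default.lung.mask, truth.geometry.lung_mask) >= 0.7

    def test_noise_free_lung_stays_inside_the_true_lung(self, processed_clean,
                                                        clean_recording):
        from scipy import ndimage
        truth = clean_recording[3]
        dilated = ndimage.binary_dilation(truth.geometry.lung_mask)
        assert not (processed_clean.lung.mask & ~dilated).any()

    def test_heart_covering_everything_is_an_error(self, default_recording):
        _, movie, _, _ = default_recording
        from eitsep.filtering import RateEstimate, refine_movies
        p = default_recording[0]
        rates = RateEstimate(f_RR=p.f_RR, f_HR=p.f_HR, resp_peak_power=1,
                             cardiac_peak_power=1)
        resp_m, _, _ = refine_movies(movie, rates)
        everything = RegionMask(np.ones(movie.grid_shape, dtype=bool), "heart")
        with pytest.raises(ValueError, match="empty lung"):
            lung_mask(resp_m, everything)


class TestStabilityAndExports:
    def test_heart_masks_agree_across_noise_replicates(self):
        geometry = make_geometry(16, seed=21)
        masks = []
        for rep_seed in (100, 101, 102):
            p = SimulationParams(seed=rep_seed, breathing_duration=22.0,
                                 apnea_duration=6.0, f_RR=0.318, f_HR=1.43)
            movie, flow, _ = simulate_recording(p, geometry, dtype=np.float32)
            masks.append(process_recording(movie, flow).heart.mask)
        for a in masks:
            for b in masks:
                assert dice(a, b) >= 0.8

    def test_rle_round_trip(self):
        rng = np.random.default_rng(1)
        mask = RegionMask(rng.random((10, 10)) > 0.6, "lung")
        rebuilt = np.zeros((10, 10), dtype=bool)
        for r, start, length in mask_to_rle(mask):
            rebuilt[r, start:start + length] = True
        np.testing.assert_array_equal(rebuilt, mask.mask)
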