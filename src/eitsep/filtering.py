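"""Spectral separation of cardiac and respiratory impedance signals.

The separation runs in two stages.  First a *rough* split with fixed
physiological bands — 2-40 bpm for respiration, 40-400 bpm for cardiac
activity — accentuates each component in the mean lung signal so that
periodogram peak detection can estimate the respiratory rate ``f_RR`` and
heart rate ``f_HR``.  Those rates then parameterize *refined* zero-phase
band-pass filters applied to every pixel time trace, producing three
filtered movies:

* respiratory:      [0.5, 2.5] * f_RR
* cardiac:          [0.5, 2.5] * f_HR
* cardiac (strict): [0.8, 1.2] * f_HR

All filters are linear-phase FIR (windowed-sinc, Hamming) applied
forward-backward, so the output has zero group delay and amplitudes are
preserved across the pass-band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import irfft, next_fast_len, rfft

from .io import PixelMovie

#: rough physiological search bands, Hz (2-40 bpm and 40-400 bpm)
ROUGH_RESP_BAND = (2.0 / 60.0, 40.0 / 60.0)
ROUGH_CARDIAC_BAND = (40.0 / 60.0, 400.0 / 60.0)

#: fraction of Nyquist at which the upper cardiac cutoff is capped
NYQUIST_CAP = 0.95

#: periodogram peak must exceed this multiple of the in-band median power
PEAK_TO_MEDIAN_FLOOR = 20.0

#: Hamming-window FIR: transition width ~= 3.3 * fs / n_taps
_HAMMING_TBW = 3.3

#: transition width as a fraction of the lower band edge
_TRANSITION_FRAC = 0.3


@dataclass(frozen=True)
class BandSpec:
    """Pass-band in Hz."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"need 0 < low < high, got [{self.low}, {self.high}]")

    def validate(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band edge {self.high} Hz exceeds Nyquist {fs / 2} Hz"
            )


@dataclass
class RateEstimate:
    """Detected respiratory and heart rates with harmonic-conflict status."""

    f_RR: float
    f_HR: float
    resp_peak_power: float
    cardiac_peak_power: float
    harmonic_conflict: bool = False
    conflict_resolution: str = "none"  # none | next_peak | unresolved


# ---------------------------------------------------------------------------
# filter design and zero-phase application
# ---------------------------------------------------------------------------

def design_bandpass(
    band: BandSpec,
    fs: float,
    order: int | None = None,
    max_order: int | None = None,
) -> np.ndarray:
    """Linear-phase FIR band-pass coefficients (windowed-sinc, Hamming).

    The default order is the smallest odd integer giving a transition width
    of ``0.3 * band.low``; ``max_order`` caps it (long recordings are not
    needed to resolve narrow respiratory bands when the signal itself is
    short).  The design cutoffs are widened by half the realized transition
    width so the nominal band edges sit at ~unity gain, and the stop band
    reaches >= 40 dB attenuation one transition width outside the band.
    """
    band.validate(fs)
    if order is None:
        order = int(np.ceil(_HAMMING_TBW * fs / (_TRANSITION_FRAC * band.low)))
    if max_order is not None:
        order = min(order, max_order)
    order = max(order, 11)
    if order % 2 == 0:
        order += 1
    trans = _HAMMING_TBW * fs / order
    lo = max(band.low - trans / 2, 0.5 * band.low)
    hi = min(band.high + trans / 2, band.high + 0.49 * (fs / 2 - band.high))
    return sps.firwin(order, [lo, hi], window="hamming", pass_zero=False, fs=fs)


def apply_zero_phase(x: np.ndarray, coefficients: np.ndarray, axis: int = 0) -> np.ndarray:
    """Forward-backward FIR filtering with reflection-padded edges.

    Because the coefficients are symmetric (linear phase), forward-backward
    application equals convolving twice; it is performed in one FFT pass by
    multiplying with the squared frequency response.  The result has zero
    group delay: an in-band sinusoid's input/output cross-correlation peaks
    at lag 0.
    """
    x = np.asarray(x)
    dtype = x.dtype if np.issubdtype(x.dtype, np.floating) else np.float64
    taps = np.asarray(coefficients, dtype=dtype)
    x = x.astype(dtype, copy=False)
    L = taps.size
    n = x.shape[axis]
    if n <= 3 * L:
        raise ValueError(
            f"signal length {n} too short for zero-phase filtering: "
            f"need > 3 * filter length = {3 * L}"
        )
    x = np.moveaxis(x, axis, 0)
    pad_width = [(L, L)] + [(0, 0)] * (x.ndim - 1)
    xp = np.pad(x, pad_width, mode="reflect")
    m = xp.shape[0]
    nfft = next_fast_len(m + 2 * L)
    X = rfft(xp, nfft, axis=0)
    H2 = rfft(taps, nfft) ** 2
    y = irfft(X * H2.reshape((-1,) + (1,) * (x.ndim - 1)), nfft, axis=0)
    y = y[L - 1 + L : L - 1 + L + n]  # double-pass delay + pad removal
    return np.moveaxis(y, 0, axis)


def _zero_phase_batch(x: np.ndarray, taps_list) -> list[np.ndarray]:
    """Zero-phase filter one (n, m) array with several kernels, sharing the FFT."""
    n = x.shape[0]
    l_max = max(t.size for t in taps_list)
    if n <= 3 * l_max:
        raise ValueError(
            f"signal length {n} too short for zero-phase filtering: "
            f"need > 3 * filter length = {3 * l_max}"
        )
    dtype = x.dtype if np.issubdtype(x.dtype, np.floating) else np.float64
    x = x.astype(dtype, copy=False)
    xp = np.pad(x, ((l_max, l_max), (0, 0)), mode="reflect")
    # the double-pass convolution tail may wrap circularly by up to l_max - 2
    # samples; it lands inside the pad region, ahead of the cropped output
    nfft = next_fast_len(xp.shape[0] + l_max)
    X = rfft(xp, nfft, axis=0)
    outs = []
    for taps in taps_list:
        H2 = rfft(np.asarray(taps, dtype=dtype), nfft) ** 2
        y = irfft(X * H2[:, None], nfft, axis=0)
        start = (taps.size - 1) + l_max
        outs.append(y[start:start + n])
    return outs


def frequency_response(coefficients: np.ndarray, fs: float, n: int = 8192):
    """(freqs_Hz, |H|) of a single forward pass of the designed filter."""
    w, h = sps.freqz(coefficients, worN=n, fs=fs)
    return w, np.abs(h)


# ---------------------------------------------------------------------------
# rough split and rate detection
# ---------------------------------------------------------------------------

def _max_order_for(n: int) -> int:
    return (n - 1) // 3 - 1


def rough_split(
    movie: PixelMovie,
    region: np.ndarray,
    segment: str = "breathing",
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-region signal roughly band-passed into respiratory and cardiac parts."""
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty region mask")
    seg = movie.segment(segment)
    trace = movie.mean_trace(region)[seg.start:seg.end]
    fs = movie.fs
    cap = _max_order_for(trace.size)
    resp_band = BandSpec(*ROUGH_RESP_BAND)
    cardiac_band = BandSpec(
        ROUGH_CARDIAC_BAND[0], min(ROUGH_CARDIAC_BAND[1], NYQUIST_CAP * fs / 2)
    )
    resp = apply_zero_phase(trace, design_bandpass(resp_band, fs, max_order=cap))
    cardiac = apply_zero_phase(trace, design_bandpass(cardiac_band, fs, max_order=cap))
    return resp, cardiac


def _band_peak(freqs, power, band: BandSpec, name: str) -> tuple[float, float]:
    in_band = (freqs >= band.low) & (freqs <= band.high)
    p = power[in_band]
    f = freqs[in_band]
    floor = PEAK_TO_MEDIAN_FLOOR * np.median(p)
    if p.max() < floor or p.max() <= 0:
        raise ValueError(
            f"no spectral peak above the noise floor in the {name} band "
            f"[{band.low:.3f}, {band.high:.3f}] Hz"
        )
    i = int(np.argmax(p))
    return float(f[i]), float(p[i])


def estimate_rates(
    resp_signal: np.ndarray,
    cardiac_signal: np.ndarray,
    fs: float,
    resp_band: BandSpec | None = None,
    cardiac_band: BandSpec | None = None,
) -> RateEstimate:
    """Periodogram peak detection of f_RR and f_HR with harmonic screening.

    The periodograms use a rectangular window, linear detrend and 4x
    zero-padding for peak interpolation; "one bin" for the harmonic-conflict
    test is the physical resolution ``fs / len(signal)``.  When the cardiac
    peak sits within one bin of an integer multiple of f_RR the conflict
    flag is set; the estimate moves to the strongest non-harmonic peak if
    that peak holds at least half the in-band maximum power, otherwise the
    conflict stays unresolved (mirrors manual inspection).
    """
    resp_band = resp_band or BandSpec(*ROUGH_RESP_BAND)
    cardiac_band = cardiac_band or BandSpec(
        ROUGH_CARDIAC_BAND[0], min(ROUGH_CARDIAC_BAND[1], NYQUIST_CAP * fs / 2)
    )
    n = len(resp_signal)
    if n < 20 * fs:
        raise ValueError("need >= 20 s of signal for rate estimation")
    bin_hz = fs / n

    def pgram(x):
        return sps.periodogram(x, fs=fs, window="boxcar", detrend="linear",
                               nfft=4 * len(x))

    f_r, p_r = pgram(np.asarray(resp_signal, dtype=float))
    f_c, p_c = pgram(np.asarray(cardiac_signal, dtype=float))
    f_RR, resp_power = _band_peak(f_r, p_r, resp_band, "respiratory")
    f_HR, cardiac_power = _band_peak(f_c, p_c, cardiac_band, "cardiac")

    harmonics = np.arange(2, int(cardiac_band.high / f_RR) + 2) * f_RR
    conflict = bool(np.any(np.abs(f_HR - harmonics) < bin_hz))
    resolution = "none"
    if conflict:
        resolution = "unresolved"
        in_band = (f_c >= cardiac_band.low) & (f_c <= cardiac_band.high)
        fb, pb = f_c[in_band], p_c[in_band]
        peaks, _ = sps.find_peaks(pb)
        ok = [i for i in peaks
              if np.abs(fb[i] - harmonics).min() >= bin_hz]
        if ok and pb[ok].max() >= 0.5 * pb.max():
            j = ok[int(np.argmax(pb[ok]))]
            f_HR, cardiac_power = float(fb[j]), float(pb[j])
            resolution = "next_peak"
    return RateEstimate(
        f_RR=f_RR, f_HR=f_HR,
        resp_peak_power=resp_power, cardiac_peak_power=cardiac_power,
        harmonic_conflict=conflict, conflict_resolution=resolution,
    )


# ---------------------------------------------------------------------------
# refined per-pixel filtering
# ---------------------------------------------------------------------------

def refined_bands(
    rates: RateEstimate,
    fs: float,
    refine_factors: tuple[float, float] = (0.5, 2.5),
    strict_factors: tuple[float, float] = (0.8, 1.2),
) -> tuple[BandSpec, BandSpec, BandSpec]:
    """Respiratory / cardiac / strict-cardiac refined bands at the given rates.

    The respiratory upper edge is capped below the cardiac lower edge when
    the two would overlap (e.g. slow heart over fast breathing).
    """
    lo_r, hi_r = refine_factors[0] * rates.f_RR, refine_factors[1] * rates.f_RR
    lo_c = refine_factors[0] * rates.f_HR
    hi_c = min(refine_factors[1] * rates.f_HR, NYQUIST_CAP * fs / 2)
    if hi_r >= lo_c:
        hi_r = 0.9 * lo_c
    resp = BandSpec(lo_r, hi_r)
    cardiac = BandSpec(lo_c, hi_c)
    strict = BandSpec(strict_factors[0] * rates.f_HR,
                      min(strict_factors[1] * rates.f_HR, NYQUIST_CAP * fs / 2))
    return resp, cardiac, strict


def refine_movies(
    movie: PixelMovie,
    rates: RateEstimate,
    refine_factors: tuple[float, float] = (0.5, 2.5),
    strict_factors: tuple[float, float] = (0.8, 1.2),
) -> tuple[PixelMovie, PixelMovie, PixelMovie]:
    """Filter every pixel trace into the three refined movies.

    Raises when the rate estimate carries an unresolved harmonic conflict:
    the caller must supply a manual rate override (the automated analogue of
    visual heart-rate inspection).
    """
    if rates.harmonic_conflict and rates.conflict_resolution == "unresolved":
        raise ValueError(
            "unresolved respiratory-harmonic/heart-rate conflict: supply a manual "
            "rate override (e.g. RateEstimate with corrected f_HR)"
        )
    fs = movie.fs
    bands = refined_bands(rates, fs, refine_factors, strict_factors)
    cap = _max_order_for(movie.n_frames)
    flat = movie.data.reshape(movie.n_frames, -1)
    taps_list = []
    for band in bands:
        taps = design_bandpass(band, fs, max_order=cap)
        if _HAMMING_TBW * fs / taps.size > 2 * band.low:
            warnings.warn(
                f"recording too short for a sharp [{band.low:.3f}, {band.high:.3f}] Hz "
                "band; transition width degraded"
            )
        taps_list.append(taps)
    # constant pixel traces band-pass to exactly zero (no DC gain): skip them
    active = np.ptp(flat, axis=0) > 0
    filtered = _zero_phase_batch(np.ascontiguousarray(flat[:, active]), taps_list)
    out = []
    for y in filtered:
        full = np.zeros(flat.shape, dtype=y.dtype)
        full[:, active] = y
        out.append(movie.with_data(
            full.reshape(movie.data.shape).astype(movie.data.dtype, copy=False)))
    return tuple(out)
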