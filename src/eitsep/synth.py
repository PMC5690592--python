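"""Synthetic thorax-movie generator with known ground truth.

Emulates the output of dynamic EIT reconstruction — an ``N x H x W`` movie of
impedance changes on a (default) 32x32 grid — for a recording protocol of
spontaneous breathing followed by a short apnea:

* two lateral lung regions carry a respiratory component (raised-cosine
  breath shape at ``f_RR``) plus a smaller multi-harmonic cardiac component
  at ``f_HR``;
* a ventral heart region carries the cardiac waveform shifted by 150-180
  degrees (at the cardiac fundamental) with its own, larger amplitude;
* remaining in-body pixels carry additive Gaussian noise only; pixels
  outside the body outline are exactly zero (reconstruction support);
* a synchronized spirometric flow trace is the analytic time derivative of
  a volume signal whose per-breath excursion is a known tidal volume.

Everything realized per cycle (rates, amplitudes, cycle boundaries, tidal
volumes) is recorded in a :class:`GroundTruth` sidecar so every downstream
stage can be tested without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .io import FlowTrace, PixelMovie, Segment, write_recording

#: relative amplitudes of the cardiac fundamental and its 2nd/3rd harmonics
CARDIAC_HARMONICS = (1.0, 0.5, 0.1)

MIN_GRID = 16


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThoraxGeometry:
    """Binary anatomy masks on a square pixel grid.

    ``background_mask`` is the in-body area not claimed by lung or heart;
    pixels outside the body outline belong to no mask.
    """

    grid_size: int
    lung_mask: np.ndarray
    heart_mask: np.ndarray
    background_mask: np.ndarray

    def __post_init__(self) -> None:
        if (self.lung_mask & self.heart_mask).any():
            raise ValueError("lung and heart masks overlap")

    @property
    def body_mask(self) -> np.ndarray:
        return self.lung_mask | self.heart_mask | self.background_mask


def _ellipse(grid: int, center: tuple[float, float], semi: tuple[float, float]) -> np.ndarray:
    r, c = np.ogrid[:grid, :grid]
    return ((r - center[0]) / semi[0]) ** 2 + ((c - center[1]) / semi[1]) ** 2 <= 1.0


def make_geometry(grid_size: int = 32, seed: int = 0) -> ThoraxGeometry:
    """Two ellipsoidal lateral lungs plus one ventral-central heart.

    Deterministic given ``seed``; the seed applies a small jitter to organ
    centers and axes so cohorts get per-subject anatomy.  Row 0 is ventral.
    """
    if grid_size < MIN_GRID:
        raise ValueError(
            f"grid_size {grid_size} too small: three disjoint regions need >= {MIN_GRID}"
        )
    rng = np.random.default_rng(seed)
    g = float(grid_size)
    jit = lambda scale: rng.uniform(-scale, scale) * g  # noqa: E731

    body = _ellipse(grid_size, ((g - 1) / 2, (g - 1) / 2), (0.48 * g, 0.48 * g))
    lungs = np.zeros((grid_size, grid_size), dtype=bool)
    for col_frac in (0.28, 0.72):
        lungs |= _ellipse(
            grid_size,
            (0.58 * g + jit(0.01), col_frac * g + jit(0.01)),
            (0.23 * g + jit(0.008), 0.14 * g + jit(0.008)),
        )
    heart = _ellipse(
        grid_size,
        (0.28 * g + jit(0.01), 0.52 * g + jit(0.01)),
        (0.105 * g + jit(0.006), 0.115 * g + jit(0.006)),
    )
    lungs &= body
    heart &= body
    heart &= ~lungs  # jitter safety: heart wins nothing, lungs keep their pixels
    n_lung_parts = ndimage.label(lungs)[1]
    if heart.sum() < 4 or lungs.sum() < 8 or n_lung_parts != 2:
        raise ValueError("grid too coarse for three disjoint anatomical regions")
    return ThoraxGeometry(
        grid_size=grid_size,
        lung_mask=lungs,
        heart_mask=heart,
        background_mask=body & ~lungs & ~heart,
    )


# ---------------------------------------------------------------------------
# simulation parameters
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Physiology and acquisition knobs for one synthetic recording.

    Amplitudes are peak-to-trough *half*-amplitudes in arbitrary impedance
    units: the respiratory lung signal swings ``2*resp_amplitude`` per
    breath and the cardiac lung signal ``2*cardiac_amplitude`` per beat
    (one order of magnitude smaller by default).  The heart region carries
    the cardiac waveform delayed by ``heart_phase_shift`` degrees at the
    cardiac fundamental, scaled by ``heart_amplitude_factor``.
    """

    fs: float = 44.0
    breathing_duration: float = 45.0
    apnea_duration: float = 15.0
    f_RR: float = 0.25
    f_HR: float = 1.1
    resp_amplitude: float = 1.0
    cardiac_amplitude: float | None = None  # default resp_amplitude / 10
    heart_amplitude_factor: float = 2.0
    heart_phase_shift: float = 165.0
    noise_sd: float = 0.01
    rate_jitter_cv: float = 0.03
    amp_jitter_cv: float = 0.03
    psf_sigma: float = 0.0
    tidal_volume: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cardiac_amplitude is None:
            self.cardiac_amplitude = self.resp_amplitude / 10.0
        if self.fs <= 2 * (2.5 * self.f_HR):
            raise ValueError("fs must exceed twice the refined cardiac band edge (5*f_HR)")
        if not self.cardiac_amplitude < self.resp_amplitude:
            raise ValueError("cardiac_amplitude must be smaller than resp_amplitude")
        if not 150.0 <= self.heart_phase_shift <= 180.0:
            raise ValueError("heart_phase_shift must lie in [150, 180] degrees")
        if self.breathing_duration <= 0 or self.apnea_duration < 0:
            raise ValueError("durations must be positive (apnea may be zero)")
        if self.noise_sd < 0 or self.psf_sigma < 0:
            raise ValueError("noise_sd and psf_sigma must be non-negative")


@dataclass
class GroundTruth:
    """Realized per-cycle truths for one simulated recording."""

    geometry: ThoraxGeometry
    true_f_RR: float
    true_f_HR: float
    true_resp_amplitude_per_cycle: list[float]
    true_cardiac_amplitude_per_cycle: list[float]
    true_heart_phase_shift: float
    true_tidal_volumes: list[float]
    breath_bounds: list[tuple[int, int]] = field(default_factory=list)
    beat_bounds: list[tuple[int, int]] = field(default_factory=list)

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "true_f_RR": self.true_f_RR,
            "true_f_HR": self.true_f_HR,
            "true_resp_amplitude_per_cycle": self.true_resp_amplitude_per_cycle,
            "true_cardiac_amplitude_per_cycle": self.true_cardiac_amplitude_per_cycle,
            "true_heart_phase_shift": self.true_heart_phase_shift,
            "true_tidal_volumes": self.true_tidal_volumes,
            "breath_bounds": [list(b) for b in self.breath_bounds],
            "beat_bounds": [list(b) for b in self.beat_bounds],
            "lung_mask": self.geometry.lung_mask.astype(int).tolist(),
            "heart_mask": self.geometry.heart_mask.astype(int).tolist(),
        }


# ---------------------------------------------------------------------------
# waveform construction
# ---------------------------------------------------------------------------

def _jittered_periods(rng, nominal: float, total: float, cv: float) -> np.ndarray:
    """Successive cycle periods with truncated-Gaussian multiplicative jitter."""
    n_max = int(np.ceil(total / nominal * 1.5)) + 4
    z = np.clip(rng.standard_normal(n_max), -3, 3)
    return nominal * (1.0 + cv * z)


def cardiac_waveform(phase: np.ndarray) -> np.ndarray:
    """Multi-harmonic cardiac pulse, unit fundamental, as a function of phase."""
    w = np.zeros_like(phase)
    for h, c in enumerate(CARDIAC_HARMONICS, start=1):
        w += c * np.cos(h * phase)
    return w


def _cardiac_pp() -> float:
    """Peak-to-trough of the unit cardiac waveform over one period."""
    phi = np.linspace(0, 2 * np.pi, 4096)
    w = cardiac_waveform(phi)
    return float(w.max() - w.min())


def simulate_recording(
    params: SimulationParams,
    geometry: ThoraxGeometry | None = None,
    subject_id: str = "S00",
    position: str = "upright",
    replicate: int = 1,
    dtype=np.float64,
) -> tuple[PixelMovie, FlowTrace, GroundTruth]:
    """Generate one recording (movie, flow, ground truth); reproducible by seed."""
    if geometry is None:
        geometry = make_geometry(seed=params.seed)
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    n_b = int(round(params.breathing_duration * fs))
    n_a = int(round(params.apnea_duration * fs))
    n = n_b + n_a
    t = np.arange(n) / fs

    # --- respiration: an integer number of raised-cosine breaths scaled to
    # fill the breathing segment exactly, so the trace is periodic right up
    # to the apnea transition (no artificial quiet gap that would distort
    # the last filtered cycle)
    periods = _jittered_periods(rng, 1.0 / params.f_RR, params.breathing_duration,
                                params.rate_jitter_cv)
    cum = np.cumsum(periods)
    m = int(np.searchsorted(cum, params.breathing_duration, side="right"))
    # nearest breath count: stretch or compress by at most half a breath
    if m < cum.size and (cum[m] - params.breathing_duration
                         < params.breathing_duration - cum[m - 1]):
        m += 1
    if m < 3:
        raise ValueError(
            f"breathing segment holds only {m} full breaths; need >= 3"
        )
    periods = periods[:m] * (params.breathing_duration / cum[m - 1])
    breaths = list(zip(np.concatenate([[0.0], np.cumsum(periods[:-1])]), periods))
    amp_z = np.clip(rng.standard_normal(len(breaths)), -3, 3)
    breath_amp = params.resp_amplitude * (1.0 + params.amp_jitter_cv * amp_z)
    breath_vt = params.tidal_volume * (1.0 + params.amp_jitter_cv * amp_z)

    resp = np.zeros(n)
    volume = np.zeros(n)
    flow = np.zeros(n)
    breath_bounds: list[tuple[int, int]] = []
    true_resp_pp: list[float] = []
    true_vt: list[float] = []
    for (t0, T), a, vt in zip(breaths, breath_amp, breath_vt):
        i0, i1 = int(np.ceil(t0 * fs)), int(np.ceil((t0 + T) * fs))
        i1 = min(i1, n_b)
        tt = t[i0:i1] - t0
        shape = 0.5 * (1.0 - np.cos(2 * np.pi * tt / T))
        resp[i0:i1] = 2.0 * a * shape
        volume[i0:i1] = vt * shape
        flow[i0:i1] = vt * (np.pi / T) * np.sin(2 * np.pi * tt / T)
        breath_bounds.append((i0, i1))
        true_resp_pp.append(2.0 * a)
        true_vt.append(vt)

    # --- cardiac phase: piecewise-linear through jittered beat boundaries,
    # extended before t=0 so the delayed heart trace can be interpolated.
    lead = 2.0 / params.f_HR
    beat_T = _jittered_periods(rng, 1.0 / params.f_HR, t[-1] + 2 * lead,
                               params.rate_jitter_cv)
    beat_edges = np.concatenate([[0.0], np.cumsum(beat_T)]) - lead
    beat_phase = 2 * np.pi * np.arange(beat_edges.size)
    phase_at = lambda times: np.interp(times, beat_edges, beat_phase)  # noqa: E731

    pp = _cardiac_pp()
    scale = 2.0 * params.cardiac_amplitude / pp
    cardiac_lung = scale * cardiac_waveform(phase_at(t))
    delay = params.heart_phase_shift / 360.0 / params.f_HR
    cardiac_heart = (params.heart_amplitude_factor * scale
                     * cardiac_waveform(phase_at(t - delay)))

    beat_bounds: list[tuple[int, int]] = []
    true_cardiac_pp: list[float] = []
    for e0, e1 in zip(beat_edges[:-1], beat_edges[1:]):
        i0, i1 = int(np.ceil(e0 * fs)), int(np.ceil(e1 * fs))
        if i0 < 0 or i1 > n:
            continue
        beat_bounds.append((i0, i1))
        seg = cardiac_lung[i0:i1]
        true_cardiac_pp.append(float(seg.max() - seg.min()))

    # --- assemble movie
    data = np.zeros((n,) + geometry.lung_mask.shape)
    data[:, geometry.lung_mask] = (resp + cardiac_lung)[:, None]
    data[:, geometry.heart_mask] = cardiac_heart[:, None]
    if params.noise_sd > 0:
        body = geometry.body_mask
        noise_dtype = np.float32 if dtype == np.float32 else np.float64
        data[:, body] += params.noise_sd * rng.standard_normal(
            (n, int(body.sum())), dtype=noise_dtype)
    if params.psf_sigma > 0:
        data = ndimage.gaussian_filter(data, sigma=(0, params.psf_sigma, params.psf_sigma))

    segments = [Segment("breathing", 0, n_b)]
    if n_a > 0:
        segments.append(Segment("apnea", n_b, n))
    movie = PixelMovie(
        data=data.astype(dtype, copy=False), fs=fs, subject_id=subject_id,
        position=position, replicate=replicate, segments=segments,
    )
    flow_trace = FlowTrace(flow, fs)

    total_breath_time = sum(T for _, T in breaths)
    beats_in = [(e0, e1) for e0, e1 in zip(beat_edges[:-1], beat_edges[1:])
                if e0 >= 0 and e1 <= t[-1]]
    truth = GroundTruth(
        geometry=geometry,
        true_f_RR=len(breaths) / total_breath_time,
        true_f_HR=len(beats_in) / sum(e1 - e0 for e0, e1 in beats_in),
        true_resp_amplitude_per_cycle=true_resp_pp,
        true_cardiac_amplitude_per_cycle=true_cardiac_pp,
        true_heart_phase_shift=params.heart_phase_shift,
        true_tidal_volumes=true_vt,
        breath_bounds=breath_bounds,
        beat_bounds=beat_bounds,
    )
    return movie, flow_trace, truth


def write_synthetic_recording(path, params: SimulationParams, **kwargs):
    """Simulate and persist one recording plus its ground-truth sidecar."""
    movie, flow, truth = simulate_recording(params, **kwargs)
    write_recording(path, movie, flow, ground_truth=truth.to_json_dict())
    return movie, flow, truth
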