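"""Spatial separation of heart and lung by cross-correlation phase mapping.

Cardiac-band impedance changes inside the heart are phase-shifted by
roughly 150-180 degrees relative to cardiac-related changes inside the
lung.  The procedure exploits this: pick a lung reference region (the pixel
of maximal respiratory-band temporal variation plus its 4-connected
neighbours), cross-correlate every pixel's cardiac-band trace with the mean
reference signal over one centered cardiac period of lags, convert the lag
of maximal correlation to a phase angle, threshold at +/-30 degrees, and
clean the resulting binary image with morphological closing and opening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from .io import PixelMovie

#: 3x3 cross structuring element (4-connectivity), used for morphology and labeling
CROSS = ndimage.generate_binary_structure(2, 1)

#: phase threshold in degrees separating heart from lung pixels
PHASE_THRESHOLD_DEG = 30.0

#: pixels with cardiac-band std below this fraction of the reference's are invalid
VALIDITY_FLOOR = 0.10

#: lung pixels: respiratory-band std above this fraction of the grid maximum
LUNG_STD_FRACTION = 0.25


@dataclass
class RegionMask:
    """Binary mask with a semantic kind: lung, heart or reference."""

    mask: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.kind not in ("lung", "heart", "reference"):
            raise ValueError(f"unknown mask kind {self.kind!r}")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class PhaseMap:
    """Per-pixel phase (degrees, (-180, 180]) and peak correlation."""

    phase: np.ndarray
    correlation: np.ndarray
    valid: np.ndarray


# ---------------------------------------------------------------------------
# reference region
# ---------------------------------------------------------------------------

def find_reference_region(resp_movie: PixelMovie) -> RegionMask:
    """Maximal-variation pixel of the respiratory-filtered movie + 4-neighbours.

    The respiratory-band standard deviation peaks inside the lung, so the
    winning pixel (ties broken in row-major order) anchors a lung reference;
    neighbours outside the grid are clipped.
    """
    std = resp_movie.data.std(axis=0)
    if not np.any(std > 0):
        raise ValueError("all-zero movie: no reference region")
    r, c = np.unravel_index(int(np.argmax(std)), std.shape)
    mask = np.zeros(std.shape, dtype=bool)
    for dr, dc in ((0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)):
        rr, cc = r + dr, c + dc
        if 0 <= rr < std.shape[0] and 0 <= cc < std.shape[1]:
            mask[rr, cc] = True
    return RegionMask(mask, "reference")


# ---------------------------------------------------------------------------
# phase map
# ---------------------------------------------------------------------------

def compute_phase_map(
    cardiac_movie: PixelMovie,
    reference: RegionMask,
    f_HR: float,
) -> PhaseMap:
    """Normalized cross-correlation phase of every pixel vs the lung reference.

    Lags span one centered cardiac period ``T = fs / f_HR`` frames; the lag
    of maximal correlation maps to ``360 * lag / T`` degrees in (-180, 180].
    Positive phase means the pixel waveform lags the reference.  Pixels
    whose cardiac-band std is below 10% of the reference region's are marked
    invalid (background noise).
    """
    if reference.n_pixels == 0:
        raise ValueError("empty reference region")
    fs = cardiac_movie.fs
    T = fs / f_HR
    if T < 4:
        raise ValueError(
            f"cardiac period {T:.1f} frames too short for phase mapping (need >= 4)"
        )
    half = int(round(T / 2))
    ref = cardiac_movie.mean_trace(reference.mask)
    n = cardiac_movie.n_frames
    flat = cardiac_movie.data.reshape(n, -1)
    t0, t1 = half, n - half
    if t1 - t0 < 2 * T:
        raise ValueError("movie too short for the lag search window")

    r = ref[t0:t1] - ref[t0:t1].mean()
    r_norm = np.linalg.norm(r)
    lags = np.arange(-half, half + 1)
    m = t1 - t0
    # one matrix product gives every (pixel, lag) numerator: column i of R is
    # the centered reference placed at offset t0+lag_i (r sums to zero, so no
    # per-window mean correction is needed)
    R = np.zeros((n, lags.size), dtype=flat.dtype)
    for i, lag in enumerate(lags):
        R[t0 + lag : t1 + lag, i] = r
    numer = (flat.T @ R).T  # (lags, pixels)
    # windowed std of every pixel at every lag via cumulative sums
    zeros = np.zeros((1, flat.shape[1]))
    cs = np.concatenate([zeros, np.cumsum(flat, axis=0, dtype=np.float64)])
    ss = np.concatenate([zeros, np.cumsum(np.square(flat, dtype=np.float64), axis=0)])
    win_sum = cs[t1 + lags] - cs[t0 + lags]
    win_ssq = ss[t1 + lags] - ss[t0 + lags]
    win_var = np.clip(win_ssq - win_sum**2 / m, 0.0, None)
    denom = np.sqrt(win_var) * r_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.nan_to_num(numer / denom)

    best = np.argmax(corr, axis=0)
    best_corr = corr[best, np.arange(flat.shape[1])]
    phase = 360.0 * lags[best] / T
    phase = np.where(phase <= -180.0, phase + 360.0, phase)
    phase = np.where(phase > 180.0, phase - 360.0, phase)

    pixel_std = flat.std(axis=0)
    ref_std = float(ref.std())
    valid = pixel_std >= VALIDITY_FLOOR * ref_std

    shape = cardiac_movie.grid_shape
    return PhaseMap(
        phase=phase.reshape(shape),
        correlation=np.clip(best_corr, -1.0, 1.0).reshape(shape),
        valid=valid.reshape(shape),
    )


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def threshold_phase(phase_map: PhaseMap, threshold: float = PHASE_THRESHOLD_DEG) -> np.ndarray:
    """Raw (pre-cleanup) heart candidate pixels: valid and |phase| > threshold."""
    return phase_map.valid & (np.abs(phase_map.phase) > threshold)


def heart_mask(phase_map: PhaseMap, threshold: float = PHASE_THRESHOLD_DEG) -> RegionMask:
    """Heart mask: phase threshold, then closing + opening, largest component.

    Closing fills holes, opening removes isolated pixels (both with a 3x3
    cross); if several 4-connected components survive, the largest is kept.
    An empty mask is a legal result.
    """
    raw = threshold_phase(phase_map, threshold)
    cleaned = ndimage.binary_opening(ndimage.binary_closing(raw, CROSS), CROSS)
    labels, n = ndimage.label(cleaned, CROSS)
    if n > 1:
        sizes = ndimage.sum_labels(cleaned, labels, index=np.arange(1, n + 1))
        cleaned = labels == (1 + int(np.argmax(sizes)))
    return RegionMask(cleaned, "heart")


def lung_mask(resp_movie: PixelMovie, heart: RegionMask,
              std_fraction: float = LUNG_STD_FRACTION) -> RegionMask:
    """Lung ROI: high respiratory-band variation, minus the heart, opened.

    Pixels whose respiratory-band temporal std reaches ``std_fraction`` of
    the grid maximum, with heart pixels removed and isolated pixels cleaned
    by a 3x3-cross opening.
    """
    std = resp_movie.data.std(axis=0)
    candidate = std >= std_fraction * std.max()
    candidate &= ~heart.mask
    cleaned = ndimage.binary_opening(candidate, CROSS)
    if not cleaned.any():
        raise ValueError(
            "empty lung mask: lower std_fraction or check the respiratory movie"
        )
    return RegionMask(cleaned, "lung")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def save_mask_png(path, mask: RegionMask) -> None:
    """Binary mask as an 8-bit PNG (255 = inside)."""
    Image.fromarray((mask.mask.astype(np.uint8)) * 255).save(path)


def mask_to_rle(mask: RegionMask) -> list[tuple[int, int, int]]:
    """Row-wise run-length encoding: (row, start_col, length) per run."""
    runs = []
    for r, row in enumerate(mask.mask):
        padded = np.concatenate([[0], row.astype(int), [0]])
        d = np.diff(padded)
        starts = np.where(d == 1)[0]
        ends = np.where(d == -1)[0]
        runs.extend((r, int(s), int(e - s)) for s, e in zip(starts, ends))
    return runs


def save_phase_csv(path, phase_map: PhaseMap) -> None:
    """Phase grid as CSV (degrees; invalid pixels as nan)."""
    grid = np.where(phase_map.valid, phase_map.phase, np.nan)
    np.savetxt(path, grid, delimiter=",", fmt="%.2f")
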