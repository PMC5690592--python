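"""Recording containers and disk I/O for functional-EIT pixel movies.

A recording is a reconstructed impedance movie (``N`` frames of an ``H x W``
pixel grid, arbitrary units) with a frame rate, body-position metadata and
breathing/apnea segment labels, optionally paired with a synchronized
spirometric flow trace in L/s.  The on-disk layout is a single HDF5 file:

* dataset ``frames`` — ``(N, H, W)`` float
* dataset ``flow``   — ``(N,)`` float, L/s (optional)
* attributes ``fs``, ``subject_id``, ``position``, ``replicate`` and
  ``segments`` (JSON list of ``[label, start, end]``, 0-based half-open)

Ground truth produced by the synthetic generator travels in a JSON sidecar
(``<file>.truth.json``) so that real recordings need no extra files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
from scipy.integrate import cumulative_trapezoid

POSITIONS = ("upright", "supine", "prone", "left_lateral", "right_lateral")
SEGMENT_LABELS = ("breathing", "apnea")

MIN_DURATION_S = 5.0


@dataclass(frozen=True)
class Segment:
    """Labelled frame interval, 0-based half-open [start, end)."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad segment bounds [{self.start}, {self.end})")

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass
class PixelMovie:
    """Impedance movie: ``data`` is ``(N, H, W)`` in arbitrary units."""

    data: np.ndarray
    fs: float
    subject_id: str = "S00"
    position: str = "upright"
    replicate: int = 1
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be (N, H, W), got {self.data.shape}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_frames < MIN_DURATION_S * self.fs:
            raise ValueError(
                f"movie too short: {self.n_frames} frames < {MIN_DURATION_S} s at {self.fs} Hz"
            )
        if self.position not in POSITIONS:
            raise ValueError(f"unknown position {self.position!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        prev_end = 0
        for seg in sorted(self.segments, key=lambda s: s.start):
            if seg.start < prev_end or seg.end > self.n_frames:
                raise ValueError("segments must be non-overlapping and inside the movie")
            prev_end = seg.end

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def segment(self, label: str) -> Segment:
        """First segment with the given label; KeyError if absent."""
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(f"no {label!r} segment in recording")

    def has_segment(self, label: str) -> bool:
        return any(seg.label == label for seg in self.segments)

    def mean_trace(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Per-frame mean over ``mask`` (whole image when mask is None)."""
        if mask is None:
            return self.data.mean(axis=(1, 2))
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty region mask")
        return self.data[:, mask].mean(axis=1)

    def with_data(self, data: np.ndarray) -> "PixelMovie":
        return replace(self, data=data, segments=list(self.segments))


@dataclass
class FlowTrace:
    """Respiratory flow in L/s, sampled synchronously with a movie."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("flow must be 1-D")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return self.samples.size

    def calibrated(self, offset: float = 0.0, gain: float = 1.0) -> "FlowTrace":
        """Linear spirometer calibration: gain * (samples - offset)."""
        return FlowTrace(gain * (self.samples - offset), self.fs)


# ---------------------------------------------------------------------------
# container read / write
# ---------------------------------------------------------------------------

def write_recording(
    path: str | Path,
    movie: PixelMovie,
    flow: FlowTrace | None = None,
    ground_truth: dict | None = None,
) -> Path:
    """Write one recording (and optional ground-truth sidecar) to HDF5."""
    path = Path(path)
    if flow is not None:
        if len(flow) != movie.n_frames:
            raise ValueError(
                f"flow length {len(flow)} != frame count {movie.n_frames}"
            )
        if flow.fs != movie.fs:
            raise ValueError("flow and movie sampling frequencies differ")
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=movie.data)
        if flow is not None:
            f.create_dataset("flow", data=flow.samples)
        f.attrs["fs"] = movie.fs
        f.attrs["subject_id"] = movie.subject_id
        f.attrs["position"] = movie.position
        f.attrs["replicate"] = movie.replicate
        f.attrs["segments"] = json.dumps(
            [[s.label, s.start, s.end] for s in movie.segments]
        )
    if ground_truth is not None:
        sidecar_path(path).write_text(json.dumps(ground_truth, indent=1))
    return path


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".truth.json")


def read_recording(path: str | Path) -> tuple[PixelMovie, FlowTrace | None]:
    """Read a recording written by :func:`write_recording`.

    A missing ``flow`` dataset yields ``(movie, None)`` with a warning; a
    flow/frames length mismatch or missing mandatory metadata is an error.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "fs" not in f.attrs:
            raise ValueError(f"{path}: missing 'fs' attribute")
        if "segments" not in f.attrs:
            raise ValueError(
                f"{path}: missing 'segments' attribute; run segment labelling first"
            )
        data = f["frames"][()]
        fs = float(f.attrs["fs"])
        segments = [
            Segment(label, int(a), int(b))
            for label, a, b in json.loads(str(f.attrs["segments"]))
        ]
        movie = PixelMovie(
            data=data,
            fs=fs,
            subject_id=str(f.attrs.get("subject_id", "S00")),
            position=str(f.attrs.get("position", "upright")),
            replicate=int(f.attrs.get("replicate", 1)),
            segments=segments,
        )
        flow = None
        if "flow" in f:
            samples = f["flow"][()]
            if samples.shape[0] != movie.n_frames:
                raise ValueError(
                    f"{path}: flow length {samples.shape[0]} != frame count {movie.n_frames}"
                )
            flow = FlowTrace(samples, fs)
        else:
            warnings.warn(f"{path}: no flow channel; tidal volumes unavailable")
    return movie, flow


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(sidecar_path(path).read_text())


def export_signal_csv(path: str | Path, signal: np.ndarray, fs: float) -> Path:
    """Write a 1-D signal as a two-column CSV (time_s, value)."""
    signal = np.asarray(signal)
    t = np.arange(signal.size) / fs
    path = Path(path)
    np.savetxt(path, np.column_stack([t, signal]), delimiter=",",
               header="time_s,value", comments="")
    return path


# ---------------------------------------------------------------------------
# flow integration
# ---------------------------------------------------------------------------

def integrate_flow(flow: FlowTrace) -> np.ndarray:
    """Cumulative trapezoidal integration of flow (L/s) to volume (L).

    ``v[0] = 0`` and ``v[k]`` is the trapezoidal cumulative sum at sample
    spacing ``1/fs``.
    """
    if len(flow) == 0:
        raise ValueError("empty flow trace")
    return cumulative_trapezoid(flow.samples, dx=1.0 / flow.fs, initial=0.0)


# ---------------------------------------------------------------------------
# reference-frame subtraction
# ---------------------------------------------------------------------------

def find_stable_window(movie: PixelMovie, duration_s: float = 5.0) -> tuple[int, int]:
    """Most stable window inside the first breathing segment.

    "Stable" is operationalized as the contiguous window of the given
    duration minimizing the variance of the whole-image mean signal.
    """
    seg = movie.segment("breathing")
    win = int(round(duration_s * movie.fs))
    if seg.n_frames < win:
        raise ValueError("breathing segment shorter than the stable-window duration")
    trace = movie.mean_trace()[seg.start:seg.end]
    # sliding variance via cumulative sums
    c1 = np.concatenate([[0.0], np.cumsum(trace)])
    c2 = np.concatenate([[0.0], np.cumsum(trace**2)])
    s1 = c1[win:] - c1[:-win]
    s2 = c2[win:] - c2[:-win]
    var = s2 / win - (s1 / win) ** 2
    start = seg.start + int(np.argmin(var))
    return start, start + win


def reference_baseline(movie: PixelMovie, interval: tuple[int, int]) -> np.ndarray:
    """Per-pixel mean frame over ``interval`` (the reference baseline)."""
    a, b = interval
    _check_reference_interval(movie, a, b)
    return movie.data[a:b].mean(axis=0)


def _check_reference_interval(movie: PixelMovie, a: int, b: int) -> None:
    if b - a < movie.fs:
        raise ValueError("reference interval must span at least 1 s of frames")
    for seg in movie.segments:
        if seg.label == "breathing" and a >= seg.start and b <= seg.end:
            return
    raise ValueError("reference interval must lie inside a breathing segment")


def subtract_reference(
    movie: PixelMovie,
    mode: str = "local",
    reference_interval: tuple[int, int] | None = None,
    external_reference: np.ndarray | None = None,
) -> PixelMovie:
    """Baseline-frame subtraction for difference imaging.

    mode='local' subtracts the per-pixel mean of this movie over
    ``reference_interval`` (default: the most stable 5 s breathing window);
    mode='global' subtracts a supplied per-pixel baseline, typically taken
    from the subject's first upright recording.
    """
    if mode == "local":
        if reference_interval is None:
            reference_interval = find_stable_window(movie)
        baseline = reference_baseline(movie, reference_interval)
    elif mode == "global":
        if external_reference is None:
            raise ValueError("mode='global' requires an external_reference baseline")
        baseline = np.asarray(external_reference)
        if baseline.shape != movie.grid_shape:
            raise ValueError(
                f"baseline shape {baseline.shape} != grid {movie.grid_shape}"
            )
    else:
        raise ValueError(f"unknown reference mode {mode!r}")
    return movie.with_data(movie.data - baseline[None, :, :])
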