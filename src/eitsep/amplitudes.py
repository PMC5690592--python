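"""Per-cycle amplitude extraction and posture summaries.

Four amplitude series are extracted from the mean lung signal of one
recording:

* ``dZ_RR`` — respiratory amplitude per breath, from the respiratory-band
  movie during breathing;
* ``dZ_CR`` — cardiac amplitude per beat during breathing, from the
  [0.5, 2.5]*f_HR movie, with beat boundaries detected on the strict
  [0.8, 1.2]*f_HR trace (the strict trace is cleaner to segment, the wider
  trace preserves pulse amplitude);
* ``dZ_CA`` — cardiac amplitude per beat during apnea, from the raw
  (reference-subtracted, unfiltered) trace, boundaries again from the
  strict trace;
* ``V_T``  — tidal volume per breath from the integrated spirometric flow.

A cycle is delimited minimum-to-minimum; its amplitude is the peak-to-trough
change ``max - min`` inside the cycle.  Cycle means are averaged first per
replicate, then over the triplicate, yielding one value per subject,
position and amplitude kind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filtering import RateEstimate
from .io import FlowTrace, PixelMovie, integrate_flow

AMPLITUDE_KINDS = ("dZ_RR", "dZ_CR", "dZ_CA", "V_T")

#: consecutive extrema closer than this fraction of the cycle period are merged
MERGE_FRACTION = 0.3


@dataclass(frozen=True)
class Cycle:
    """One min-to-min cycle: [start, end) frames with interior extrema."""

    start: int
    end: int
    min_frame: int
    max_frame: int


@dataclass
class CycleAmplitudes:
    """Per-cycle peak-to-trough amplitudes of one kind for one recording."""

    kind: str
    values: np.ndarray
    cycle_bounds: list[tuple[int, int]]
    subject_id: str = "S00"
    position: str = "upright"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.kind not in AMPLITUDE_KINDS:
            raise ValueError(f"unknown amplitude kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.cycle_bounds):
            raise ValueError("values and cycle_bounds lengths differ")

    @property
    def mean(self) -> float:
        return float(self.values.mean())


# ---------------------------------------------------------------------------
# cycle detection
# ---------------------------------------------------------------------------

def _extrema(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices and types (+1 max / -1 min) of sign changes of the first difference."""
    d = np.diff(signal)
    s = np.sign(d)
    # carry the last nonzero slope through plateaus
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    change = np.where(s[1:] * s[:-1] < 0)[0] + 1
    kinds = np.where(s[change] < 0, 1, -1)  # slope turns negative at a maximum
    return change, kinds


def _merge_close(idx: np.ndarray, kinds: np.ndarray, signal: np.ndarray,
                 min_gap: float) -> tuple[list[int], list[int]]:
    """Debounce: merge extrema closer than min_gap frames, keep the more extreme;
    then enforce min/max alternation the same way."""
    out_i: list[int] = []
    out_k: list[int] = []
    for i, k in zip(idx, kinds):
        if out_i and (i - out_i[-1] < min_gap or k == out_k[-1]):
            j = out_i[-1]
            better = (k == 1 and signal[i] > signal[j]) or (k == -1 and signal[i] < signal[j])
            if out_k[-1] == k:
                if better:
                    out_i[-1] = int(i)
            else:
                # close opposite-type pair: noise wiggle; drop the newcomer
                continue
        else:
            out_i.append(int(i))
            out_k.append(int(k))
    return out_i, out_k


def detect_cycles(
    signal: np.ndarray,
    fs: float,
    f_center: float,
    boundary_signal: np.ndarray | None = None,
) -> list[Cycle]:
    """Min-to-min cycles of a band-limited trace.

    Extrema are located where the first difference changes sign; consecutive
    extrema closer than ``0.3 / f_center`` seconds are merged keeping the
    more extreme one.  Cycle boundaries come from ``boundary_signal`` when
    given (the strict-band cardiac trace), else from ``signal`` itself.
    Partial cycles at the edges are discarded; fewer than 2 complete cycles
    is an error.
    """
    ref = np.asarray(boundary_signal if boundary_signal is not None else signal,
                     dtype=float)
    signal = np.asarray(signal, dtype=float)
    if ref.shape != signal.shape:
        raise ValueError("boundary_signal must match signal length")
    min_gap = MERGE_FRACTION / f_center * fs
    idx, kinds = _extrema(ref)
    idx, kinds = _merge_close(idx, kinds, ref, min_gap)
    minima = [i for i, k in zip(idx, kinds) if k == -1]
    if len(minima) < 3:
        raise ValueError(
            f"fewer than 2 complete cycles detected (got {max(len(minima) - 1, 0)})"
        )
    cycles = []
    for a, b in zip(minima[:-1], minima[1:]):
        seg = signal[a:b + 1]
        cycles.append(Cycle(
            start=a, end=b,
            min_frame=a + int(np.argmin(seg)),
            max_frame=a + int(np.argmax(seg)),
        ))
    return cycles


def amplitude_per_cycle(signal: np.ndarray, cycles: list[Cycle]) -> np.ndarray:
    """Peak-to-trough amplitude (max - min) of ``signal`` inside each cycle."""
    signal = np.asarray(signal, dtype=float)
    return np.array([signal[c.start:c.end + 1].max() - signal[c.start:c.end + 1].min()
                     for c in cycles])


# ---------------------------------------------------------------------------
# full extraction for one recording
# ---------------------------------------------------------------------------

def extract_all(
    raw_movie: PixelMovie,
    resp_movie: PixelMovie,
    cardiac_movie: PixelMovie,
    strict_movie: PixelMovie,
    lung: np.ndarray,
    rates: RateEstimate,
    flow: FlowTrace | None = None,
) -> dict[str, CycleAmplitudes]:
    """All four amplitude series over the mean lung trace of one recording."""
    lung = np.asarray(lung, dtype=bool)
    meta = dict(subject_id=raw_movie.subject_id, position=raw_movie.position,
                replicate=raw_movie.replicate)
    breathing = raw_movie.segment("breathing")
    sl_b = slice(breathing.start, breathing.end)
    fs = raw_movie.fs

    resp_trace = resp_movie.mean_trace(lung)[sl_b]
    cardiac_trace = cardiac_movie.mean_trace(lung)[sl_b]
    strict_trace = strict_movie.mean_trace(lung)[sl_b]
    raw_trace_b = raw_movie.mean_trace(lung)[sl_b]
    # guard against fabricating beats from band leakage when no cardiac
    # component exists: a real pulse carries >~10% of the raw-trace power
    if strict_trace.std() < 1e-2 * raw_trace_b.std():
        raise ValueError("no detectable cardiac signal in the strict-band trace")

    out: dict[str, CycleAmplitudes] = {}

    breaths = detect_cycles(resp_trace, fs, rates.f_RR)
    out["dZ_RR"] = CycleAmplitudes(
        kind="dZ_RR",
        values=amplitude_per_cycle(resp_trace, breaths),
        cycle_bounds=[(c.start + breathing.start, c.end + breathing.start)
                      for c in breaths],
        **meta,
    )

    beats = detect_cycles(cardiac_trace, fs, rates.f_HR, boundary_signal=strict_trace)
    out["dZ_CR"] = CycleAmplitudes(
        kind="dZ_CR",
        values=amplitude_per_cycle(cardiac_trace, beats),
        cycle_bounds=[(c.start + breathing.start, c.end + breathing.start)
                      for c in beats],
        **meta,
    )

    if raw_movie.has_segment("apnea"):
        apnea = raw_movie.segment("apnea")
        sl_a = slice(apnea.start, apnea.end)
        raw_trace = raw_movie.mean_trace(lung)[sl_a]
        strict_apnea = strict_movie.mean_trace(lung)[sl_a]
        apnea_beats = detect_cycles(raw_trace, fs, rates.f_HR,
                                    boundary_signal=strict_apnea)
        out["dZ_CA"] = CycleAmplitudes(
            kind="dZ_CA",
            values=amplitude_per_cycle(raw_trace, apnea_beats),
            cycle_bounds=[(c.start + apnea.start, c.end + apnea.start)
                          for c in apnea_beats],
            **meta,
        )
    else:
        warnings.warn("no apnea segment: dZ_CA skipped")

    if flow is not None:
        volume = integrate_flow(flow)[sl_b]
        vol_breaths = detect_cycles(volume, fs, rates.f_RR)
        out["V_T"] = CycleAmplitudes(
            kind="V_T",
            values=amplitude_per_cycle(volume, vol_breaths),
            cycle_bounds=[(c.start + breathing.start, c.end + breathing.start)
                          for c in vol_breaths],
            **meta,
        )
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def tidy_table(amplitudes: list[CycleAmplitudes]) -> pd.DataFrame:
    """Long-format table: one row per cycle."""
    rows = []
    for amp in amplitudes:
        for i, (v, (a, b)) in enumerate(zip(amp.values, amp.cycle_bounds)):
            rows.append((amp.subject_id, amp.position, amp.replicate, amp.kind,
                         i, a, b, v))
    return pd.DataFrame(rows, columns=[
        "subject_id", "position", "replicate", "kind",
        "cycle_index", "start_frame", "end_frame", "amplitude",
    ])


def summarize(amplitudes: list[CycleAmplitudes]) -> pd.DataFrame:
    """Two-level averaging: cycles -> replicate mean -> triplicate mean.

    Returns one row per subject x position x kind, plus the derived
    ``dZ_RR_per_VT`` kind (per-replicate mean dZ_RR over mean V_T, averaged
    over replicates) wherever both ingredients exist.
    """
    if not amplitudes:
        raise ValueError("no amplitude series to summarize")
    rep = pd.DataFrame(
        [(a.subject_id, a.position, a.replicate, a.kind, a.mean) for a in amplitudes],
        columns=["subject_id", "position", "replicate", "kind", "replicate_mean"],
    )
    key = ["subject_id", "position", "replicate"]
    wide = rep.pivot_table(index=key, columns="kind", values="replicate_mean")
    if {"dZ_RR", "V_T"} <= set(wide.columns):
        ratio = (wide["dZ_RR"] / wide["V_T"]).dropna().rename("replicate_mean")
        extra = ratio.reset_index()
        extra["kind"] = "dZ_RR_per_VT"
        rep = pd.concat([rep, extra], ignore_index=True)
    summary = (
        rep.groupby(["subject_id", "position", "kind"])["replicate_mean"]
        .agg(mean_amplitude="mean", n_replicates="count")
        .reset_index()
    )
    return summary


def block_table(summary: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Subjects x positions matrix of triplicate means for one amplitude kind."""
    sub = summary[summary["kind"] == kind]
    table = sub.pivot(index="subject_id", columns="position", values="mean_amplitude")
    return table
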