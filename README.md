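# eitsep

Separation of cardiac and respiratory signals in functional electrical
impedance tomography (EIT) pixel movies.

Functional EIT monitors ventilation at the bedside by reconstructing
impedance-change images of a chest slice over time. Each lung pixel mixes a
breath-synchronous component with a pulse-synchronous component about one
order of magnitude smaller; separating the two — and separating the heart
region from cardiac-related signal inside the lung — is a prerequisite for
studying regional perfusion surrogates, for example how cardiac impedance
amplitudes change with body position. `eitsep` is aimed at researchers
analysing reconstructed EIT movies (32 × 32 pixels, ~44 Hz) with
synchronized spirometry.

The package implements:

* **Adaptive spectral separation** — rough 2–40 / 40–400 bpm band split,
  periodogram detection of the respiratory rate f_RR and heart rate f_HR
  (with respiratory-harmonic screening), then zero-phase FIR band-pass
  refinement of every pixel trace at [0.5, 2.5]·f_RR, [0.5, 2.5]·f_HR and
  [0.8, 1.2]·f_HR.
* **Heart/lung segmentation** — normalized cross-correlation of each
  pixel's cardiac-band trace against a lung reference region; the lag of
  maximal correlation becomes a phase angle, pixels beyond ±30° are heart,
  and morphological closing + opening yield a coherent mask.
* **Per-cycle amplitudes** — peak-to-trough ΔZ_RR (respiration), ΔZ_CR
  (cardiac during breathing), ΔZ_CA (cardiac during apnea, raw trace) and
  V_T (tidal volume from trapezoid-integrated flow), averaged per
  replicate and triplicate.
* **Posture statistics** — Anderson–Darling normality, Friedman
  repeated-measures test (subjects as blocks, positions as treatments),
  Conover post-hoc with Holm correction, paired Wilcoxon, Pearson.
* **A synthetic thorax-movie generator** with known ground truth (anatomy,
  rates, per-cycle amplitudes, tidal volumes), so every stage is testable
  without access to real recordings.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

```python
from eitsep import SimulationParams, simulate_recording, process_recording
from eitsep.segmentation import dice

params = SimulationParams(seed=42)          # 45 s breathing + 15 s apnea, 44 Hz
movie, flow, truth = simulate_recording(params)
result = process_recording(movie, flow)

print(f"f_RR = {result.rates.f_RR:.4f} Hz   f_HR = {result.rates.f_HR:.4f} Hz")
print(f"heart Dice {dice(result.heart.mask, truth.geometry.heart_mask):.3f}")
for kind, amp in result.amplitudes.items():
    print(f"{kind:6s} n={len(amp.values):2d}  mean={amp.mean:.4f}")
```

Output:

```
f_RR = 0.2444 Hz   f_HR = 1.1000 Hz
heart Dice 0.987
dZ_RR  n= 9  mean=2.0257
dZ_CR  n=49  mean=0.2024
dZ_CA  n=15  mean=0.2002
V_T    n= 9  mean=0.5069
```

The detected rates sit within one periodogram bin of the generated truth
(0.2444 and 1.1033 Hz). The respiratory amplitude 2.03 matches the
generated swing of 2 impedance units; the cardiac amplitude extracted by
band-pass filtering during breathing (ΔZ_CR = 0.2024) agrees with the raw
apnea amplitude (ΔZ_CA = 0.2002), i.e. the filtering itself does not bias
the cardiac amplitude; their ~10:1 ratio to ΔZ_RR reflects the generated
order-of-magnitude difference. Tidal volumes integrate back to the 0.5 L
used to synthesize the flow signal.

The same chain is available from the shell:

```bash
eitsep simulate rec.h5 --seed 42        # write one synthetic recording
eitsep filter rec.h5                    # rates + three filtered movies
eitsep segment rec.h5                   # heart/lung masks, phase map
eitsep extract rec.h5                   # tidy per-cycle amplitude CSV
eitsep run config.yaml                  # whole cohort from a YAML manifest
eitsep demo --seed 1                    # synthetic posture experiment
```

`eitsep demo` generates a 14-subject × 5-position × 3-replicate cohort in
which the cardiac amplitude of the upright and supine positions is halved,
runs the full pipeline on all 210 recordings, and reports whether the
Friedman omnibus and Conover post-hoc single out exactly those positions.

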