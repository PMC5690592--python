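# Methods

`eitsep` analyses functional EIT recordings: time series of reconstructed
impedance images (frames × 32 × 32 pixels, arbitrary units) acquired at
44 Hz during spontaneous breathing followed by a short apnea, paired with a
spirometric flow signal. The package implements the full analysis chain —
reference subtraction, adaptive spectral separation, phase-based heart
segmentation, per-cycle amplitude extraction, and repeated-measures posture
statistics — together with a synthetic thorax-movie generator that provides
ground truth for every stage.

## Signal model and separation

A lung pixel carries a mixture of a breath-synchronous component at the
respiratory rate f_RR (0.1–0.5 Hz) and a pulse-synchronous component at the
heart rate f_HR (0.8–2 Hz) roughly one order of magnitude smaller, plus
noise. Separation is adaptive and runs in two stages:

1. **Rough split.** The mean signal of a provisional lung region (top
   quartile of raw per-pixel temporal standard deviation) is band-passed
   with fixed physiological bands: 2–40 bpm (respiration) and 40–400 bpm
   (cardiac), the upper cardiac edge capped at 0.95 × Nyquist.
2. **Rate detection.** Periodograms of the two rough signals (rectangular
   window, linear detrend, 4× zero-padding for peak interpolation) give
   f_RR and f_HR as in-band power maxima. A peak counts only if it exceeds
   20× the in-band median power — for an exponential-distributed noise
   periodogram this keeps the per-band false-alarm probability near 1e-4,
   so pure noise raises an error instead of returning a rate.
3. **Refined movies.** Every pixel trace is band-passed at
   [0.5, 2.5]·f_RR (respiratory), [0.5, 2.5]·f_HR (cardiac) and
   [0.8, 1.2]·f_HR (strict cardiac). When the respiratory upper edge would
   reach the cardiac lower edge it is capped at 90% of that edge.

**Harmonic screening.** Respiratory harmonics can masquerade as the cardiac
peak. A conflict is flagged when f_HR falls within one resolution bin
(fs/N of the analysed segment; the zero-padded grid only interpolates and
does not add resolution) of an integer multiple of f_RR. On conflict the
estimate moves to the strongest non-harmonic peak if that peak holds at
least half the in-band maximum power; otherwise the recording errors out
and requires a manual rate override — the automated counterpart of visual
heart-rate inspection. Because the screen rejects a window of ±1 bin around
every harmonic, a well-posed study should not place its nominal heart rate
inside that window; the generator's default rates (below) respect this.

## Filters

All filtering uses linear-phase FIR band-passes (windowed-sinc, Hamming)
applied forward-backward, so the output has zero group delay and edge
transients are tamed by reflection padding. Because the coefficients are
symmetric, the double pass is computed in one FFT step as multiplication
with the squared magnitude response.

Design rule: transition width 0.3 × lower band edge, order =
3.3·fs/transition rounded up to odd. The order is capped so the signal is
longer than 3× the filter (a 45 s recording cannot support the thousands of
taps a 0.125 Hz edge would ask for); the realized transition width follows
from the capped order. Design cutoffs are widened by half the realized
transition width, which puts the nominal band edges at ~unity gain
(in-band sinusoids keep their amplitude within 2%) and the stop-band
―40 dB point one transition width outside the band (80 dB after the double
pass).

## Heart/lung segmentation

Cardiac impedance changes inside the heart are phase-shifted by 150–180°
relative to cardiac changes inside the lung. The segmentation exploits
this:

1. the pixel with maximal respiratory-band temporal standard deviation
   (necessarily lung tissue) plus its in-grid 4-connected neighbours form
   the reference region;
2. every pixel's cardiac-band trace is cross-correlated (normalized)
   with the mean reference signal over lags spanning one centered cardiac
   period T = fs/f_HR frames; the lag of maximal correlation maps to a
   phase in (−180°, 180°], quantized in steps of 360/T ≈ 9–16°;
3. pixels whose cardiac-band standard deviation falls below 10% of the
   reference's are marked invalid (background). This floor constrains the
   admissible pixel noise: with a cardiac peak-to-trough of 0.2 and the
   [0.5, 2.5]·f_HR band covering ~11% of the 22 Hz Nyquist range, in-band
   background noise stays under the floor only for per-pixel noise SD
   below ~0.013 — one reason the generator default is 0.01;
4. valid pixels with |phase| > 30° form the raw heart image, which is
   cleaned by morphological closing then opening with a 3×3 cross; if
   several 4-connected components survive, the largest is kept.

The sign convention is: positive phase means the pixel lags the reference.
Only |phase| is thresholded, so results do not depend on it. The lung ROI
is defined as pixels whose respiratory-band standard deviation reaches 25%
of the grid maximum, minus the heart mask, opened with the same cross; the
criterion is this package's own construction (a published lung-ROI
definition for this procedure does not exist).

## Amplitudes

All amplitudes are peak-to-trough (max − min) per cycle of the mean lung
trace. Cycles run minimum-to-minimum; extrema are sign changes of the first
difference, with consecutive extrema closer than 0.3 of the band period
merged (keeping the more extreme) to debounce noise. Four series are
extracted per recording:

* **dZ_RR** — respiratory movie, breathing segment;
* **dZ_CR** — cardiac movie, breathing segment, with beat boundaries
  detected on the strict-band trace (cleaner to segment) and amplitudes
  read from the wider band (preserves pulse shape);
* **dZ_CA** — raw (reference-subtracted, unfiltered) trace during apnea,
  boundaries again from the strict trace;
* **V_T** — per-breath excursion of the cumulative-trapezoid-integrated
  flow signal.

Cycle means are averaged per replicate, then over the triplicate, giving
one value per subject × position × kind; dZ_RR is additionally normalized
to the tidal volume per replicate (dZ_RR/V_T) before triplicate averaging.
A recording whose strict-band lung trace carries less than 1% of the raw
trace's standard deviation is rejected rather than segmented — band leakage
must not fabricate heartbeats.

## Statistics

The cohort design is repeated measures (each subject measured in every
position), so the comparisons are within-subject and nonparametric:
Anderson–Darling normality (reported only; it gates nothing), the
tie-corrected Friedman rank test across positions within subjects, Conover
post-hoc pairwise comparisons on within-block rank sums
(t distribution on (n−1)(k−1) df, |R_i − R_j| / sqrt(2n(A1 − B1)/((n−1)(k−1)))),
Holm step-down correction (Bonferroni available by config), paired
Wilcoxon signed-rank (exact for n ≤ 25 without ties), and Pearson
correlation.

For small Friedman designs (≤ 9 blocks, ≤ 5 treatments) the chi-square
tail is a poor approximation (deviations of ~0.1 from the exact permutation
p on 5×3 tables), so the p-value is computed by seeded Monte-Carlo
permutation of values within blocks (20 000 draws, within ~0.004 of exact
enumeration); larger designs use the chi-square tail, whose type-I error at
14 × 5 is calibrated to 3.5–6.5% in the test suite.

## Synthetic data generator

The generator emulates the *output* of dynamic EIT reconstruction, not the
electrical physics: no forward model, electrodes or FEM mesh. On a circular
body outline it places two lateral ellipsoidal lungs and one
ventral-central heart (seed-jittered per subject for cohort anatomy).

* **Respiration**: raised-cosine volume shape per breath; an integer number
  of breaths is scaled to fill the breathing window exactly, so the trace
  is periodic up to the apnea transition. Per-breath peak-to-trough is
  2 × resp_amplitude × (1 + jitter). The realized breath rate therefore
  snaps to (breath count)/(window length).
* **Cardiac**: harmonics (1, 0.5, 0.1) of the fundamental, phase-continuous
  across jittered beat periods, scaled to peak-to-trough
  2 × cardiac_amplitude in the lung. The 2nd harmonic makes the strict
  [0.8, 1.2]·f_HR band visibly reshape the pulse; the 3rd is small, so the
  [0.5, 2.5]·f_HR band (which keeps h1+h2) reproduces the full-waveform
  amplitude within ~4%. The heart region carries the same waveform as a
  pure time delay of heart_phase_shift degrees at the fundamental (a delay,
  not a sign flip: with even harmonics a 180° delay is not equal to
  negation), scaled by heart_amplitude_factor.
* **Flow**: the analytic derivative of the volume curve, so trapezoidal
  integration recovers the per-breath tidal volume to integration accuracy.
* **Noise**: white Gaussian on all in-body pixels; pixels outside the body
  outline are exactly zero (reconstruction support). Apnea carries cardiac
  signal and noise only.

Defaults (chosen once; units in brackets): fs 44 [Hz], breathing 45 [s],
apnea 15 [s], f_RR 0.25 [Hz], f_HR 1.1 [Hz] (66 bpm — a typical resting
rate placed ≥ 4 combined-error SDs away from every respiratory harmonic so
the default condition does not sit inside the harmonic screen's rejection
window), resp_amplitude 1 [a.u.] (swing 2), cardiac_amplitude 0.1 (one
order of magnitude smaller), heart factor 2, phase shift 165 [°], tidal
volume 0.5 [L], per-breath amplitude CV and per-cycle period CV 3%,
noise SD 0.01 [a.u.] (see the validity-floor bound above; regularized
reconstructions are smooth, so per-pixel noise well below the cardiac
signal is the realistic regime), PSF blur off.

What the generator does **not** model: reconstruction artifacts and spatial
noise correlation, cardiac-locked lung motion ("heart kick"), posture-
dependent lung shape, electrode/belt effects, drift, and amplitude
gradients within the lung. Passing tests therefore demonstrate correctness
of the *analysis chain* under the stated signal model, not robustness to
every property of real recordings.

## Demo experiment and problem sizes

`demo_experiment` builds a cohort of 14 subjects × 5 positions × 3
replicates with the cardiac amplitude of selected positions (default
upright and supine) multiplied by 0.5, runs the complete per-recording
pipeline on every movie, and checks that Friedman + Conover flag exactly
the scaled positions. Subjects get individual anatomy, rates (drawn away
from harmonic collisions on the realized-rate grid) and baseline cardiac
amplitudes (log-normal, CV ≈ 20%). Demo recordings use a 16 × 16 grid,
22 s breathing + 6 s apnea and float32 movies — a deliberately compact
problem size so that repeated cohort-level power and null calibrations
(50 and 30 runs respectively in the acceptance suite) remain cheap; all
other checks run at the full 32 × 32, 60 s default conditions.

## Numerical choices and degenerate inputs

* Ties in the reference-pixel argmax break in row-major order.
* Reference-interval "stability" = the 5 s breathing window minimizing the
  variance of the whole-image mean signal.
* Constant pixel traces are skipped during movie filtering (a band-pass
  with zero DC gain maps them to zero exactly).
* Empty heart masks are legal (no suprathreshold pixels); empty lung masks
  are an error advising a lower threshold.
* Cycle detection demands at least 2 complete min-to-min cycles.
* Pipeline cohort runs isolate per-recording failures, write all
  salvageable tables, and exit nonzero at the end if anything failed.

## Known limitations

* Phase is quantized to the lag grid (360·f_HR/fs degrees); at 44 Hz and
  1.1 Hz that is 9°, small against the 30° threshold but visible in the
  phase map.
* The harmonic screen tests proximity on the frequency grid only; it
  cannot distinguish a true rate collision from a coincidental one, which
  is why unresolved conflicts demand a manual override instead of a guess.
* The lung-ROI threshold (25% of maximal respiratory std) and the phase
  validity floor (10% of reference std) are heuristics; on data with
  strong amplitude gradients they may clip dependent lung regions.
* dZ_CA measured on the raw apnea trace inherits broadband noise; with
  noisy data its per-beat amplitudes are biased slightly upward relative
  to the band-limited dZ_CR.
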