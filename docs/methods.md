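# Methods

This note documents the models and numerical choices behind `hrvkit`, the
defaults and their units, what the synthetic generators do and do not
emulate, and the known limitations.

## Data model and units

An `RRiSeries` holds RR intervals in milliseconds; its time axis is the
cumulative sum of intervals in seconds, so an interval is stamped at the
time it *ends* (the first interval of a record ends at `values[0]/1000` s).
All sampling and resampling frequencies are in Hz, spectral densities in
ms²/Hz, band powers in ms². These conventions are applied consistently:
interpolation abscissae, sliding-window membership and segment bookkeeping
all use the end-of-interval time.

## R-peak detection

The ECG is band-pass filtered with a Butterworth filter (default passband
5–200 Hz, order 4) applied forward–backward (`sosfiltfilt`), i.e.
zero-phase: the effective magnitude response is the square of the one-pass
response and there is no group delay, so filtering cannot shift peak
latencies. The filter order and phase handling are this package's choices;
the passband is the documented default. An upper edge at or above Nyquist is
rejected rather than clipped, because silently narrowing the passband would
change detection behaviour without the user noticing (at fs ≤ 400 Hz the
200 Hz default must be lowered explicitly).

Candidates are samples where the first difference of the filtered trace
turns from positive to non-positive (a local maximum); a candidate is
accepted when the **raw** ECG sample there exceeds the user's fixed
threshold. The amplitude test deliberately uses the raw trace — the
threshold then has the units the user sees on screen. Within a 200 ms
refractory window (the physiological minimum RR interval) only the
largest-amplitude candidate is kept; without this, the zero-crossing rule
fires on noise ripples of a single QRS. There is no adaptive thresholding.
`edit_peaks` implements manual correction as a set operation; the refractory
rule is *not* re-applied to manual additions, since the user overrides the
algorithm by design.

## Artifact filters

Moving average and moving median use centered windows truncated at the
edges, preserving series length. The quotient filter flags beat *n* when its
ratio to either neighbour is ≥ 1.2 or ≤ 0.8 (inclusive thresholds);
endpoints are compared with their single neighbour. All flags are evaluated
on the original series and removals applied at once — a single deterministic
pass, no iteration. The flagged beat itself is removed (not its successor,
not both): this reading removes the ectopic interval, which is the intent of
quotient filtering, and makes the filter idempotent whenever removals do not
create new adjacent violations. Beats are removed, never interpolated or
replaced.

## Spectral pipeline

1. **Resampling.** Cubic-spline interpolation of interval values against
   their end times, evaluated on an even grid from the first to the last
   beat time at the chosen rate (default 4 Hz — comfortably above twice the
   0.4 Hz upper HF edge). The grid has `floor(span·fs)+1` points, endpoints
   inclusive. Cubic splines are the de-facto standard for tachogram
   resampling; at least 4 beats are required.
2. **Detrending.** A least-squares polynomial in time (default degree 1) is
   subtracted from the resampled series, suppressing drift that would
   otherwise leak into VLF. Detrending after resampling keeps the whole
   spectral pipeline on one grid. Degrees up to n−1 are accepted.
3. **PSD.**
   - *Welch*: P = ⌊(N−D)/S⌋+1 segments of D samples (default 256) shifted
     by S (default 128, i.e. 50% overlap); each segment is mean-removed,
     windowed (default Hann; Hamming, Kaiser β=8.6, Blackman, triangular
     and rectangular also available), optionally zero-padded, transformed;
     the one-sided densities are averaged. Density scaling compensates the
     window by its power (sum of squared coefficients), so a single-segment
     rectangular-window estimate integrates to the segment variance.
     Per-segment mean removal is this package's choice; without it, DC
     leaks into VLF through the window sidelobes. The implementation is
     `scipy.signal.welch`, whose conventions are exactly these; the test
     suite verifies the P formula and the equality with the mean of
     per-segment estimates literally.
   - *Burg AR*: reflection coefficients chosen to minimise the summed
     forward and backward prediction error at each order (Levinson update),
     default order 16. The one-sided density is 2σ²/(fs·|A(f)|²) with A the
     monic polynomial 1 + Σ aₖ z⁻ᵏ (so a process x_t = Σ φₖ x_{t−k} + e_t
     has aₖ = −φₖ) and σ² the final prediction-error power; DC and Nyquist
     are not doubled. The recursion is implemented here (SciPy has no Burg
     estimator) and cross-checked in the tests against
     `statsmodels.regression.linear_model.burg`. The frequency grid is an
     FFT of the coefficient vector zero-padded to `padded_len`
     (default 1024). A numerically zero-variance input returns a flat zero
     PSD rather than dividing by zero.
4. **Band powers.** Trapezoidal integration of the density over
   VLF/LF/HF/TP with the density linearly interpolated at the exact band
   edges, so contiguous bands tile the axis and TP = VLF + LF + HF to
   rounding. Default edges 0 / 0.04 / 0.15 / 0.4 Hz, all adjustable (a
   0.003 Hz VLF lower edge is one config change away). LF/HF is reported as
   NaN when HF = 0, and the normalized units as NaN when TP = VLF —
   missing, not infinite.

### Numerical notes

- The residual in the Parseval check (single rectangular segment, trapezoid
  vs variance) is the trapezoid's half-weight on the Nyquist bin, O(1/N) in
  expectation with χ² fluctuation; at N = 256 it stays within a few percent.
- pNN50 uses the **total** interval count N as denominator by default; the
  conventional N−1 variant is behind `denominator="n-1"`. The N form is
  never larger.
- SDSD is the centered standard deviation of the N−1 successive differences
  with denominator N−1 (population std over the differences), parallel to
  the N−1 of SDNN/RMSSD. SD1 = SDSD/√2 and SD2 = √(2·SDNN² − SDSD²/2), which
  enforce SD1² + SD2² = 2·SDNN² identically; a negative SD2 radicand within
  tolerance is clamped to 0.
- Mean HR defaults to the mean of the instantaneous rate 60000/RRiⱼ; the
  alternative 60000/mean(RRi) is behind `hr_from="mean_rri"`. The two
  differ on any non-constant series (Jensen's inequality) and both
  conventions circulate in HRV software, so the choice is explicit.

## Non-stationary analysis

Time-varying analysis windows the **beat-time axis in seconds** (default
30 s, no overlap): window k spans (k·(L−o), k·(L−o)+L], an interval belongs
to the window containing its end time, and a trailing incomplete window is
dropped (partial-window indices are biased). Windows holding fewer than two
intervals yield NaN markers. With the window set to the record duration the
result reproduces the stationary indices exactly.

Time–frequency analysis segments the **resampled series in samples**,
mirroring Welch's segmentation but keeping every sub-segment PSD
(mean-removed windowed periodogram, or per-segment Burg fit of the
mean-removed chunk). Averaging the rows reproduces the Welch estimate of
identical configuration to machine precision — this definitional
equivalence is asserted in the tests. Detrending is applied once, globally,
before segmentation; no additional per-segment polynomial detrend beyond
the mean removal.

## Synthetic generators

`make_tachogram` builds a beat sequence iteratively: the next beat time is
the previous plus the current RR value, where RR(t) = mean + Σ tones +
trend(t) + noise. The instantaneous value is evaluated at the accumulated
beat time — amplitude modulation rather than a full integral pulse frequency
modulation model. At the modulation depths used (tones ≤ 10% of the mean
interval) the analytic tone powers A²/2 are accurate ground truth for band
powers to within a few percent; at larger depths the approximation, and
hence the ground truth, degrades. Values below 1 ms are rejected as
non-positive (they would also stall the beat-time recursion). Ectopics are
planted by scaling chosen intervals after generation.

`make_ecg` plants Gaussian R-waves (default σ = 10 ms) at given beat times
on a zero baseline plus seeded white noise; beats closer than 3σ are
rejected since merged bumps have no well-defined planted peak. This is a
detection-geometry fixture, **not** a morphological ECG: no P/T waves, no
baseline wander, no realistic QRS shape. Passing detection tests on it shows
the zero-crossing/threshold/refractory logic is correct, not that the
detector is robust to real-world ECG artifacts.

`make_ar_process` simulates a stationary AR recursion (stability checked via
the companion-matrix spectral radius) with a 500-sample burn-in to remove
transient bias. `make_exercise_tachogram` ramps the mean RR linearly from
rest (900 ms) to peak exercise (350 ms) over 5 min while the HF oscillation
amplitude decays geometrically (50 → 2 ms), then recovers both
exponentially (time constant = recovery/3); noise scales with the local
amplitude so variability genuinely shrinks with intensity. These profiles
emulate the qualitative physiology (progressive vagal withdrawal, fast
vagal reactivation) but not breathing-rate drift, cadence artifacts or
measurement dropout.

What the synthetic suite cannot show: performance on real recordings with
ectopy bursts, movement artifacts, atrial fibrillation, or non-sinusoidal
spectral structure. The validation demonstrates internal correctness of the
algorithms against analytic ground truth, not clinical robustness.

## Problem sizes

The test and acceptance runs use tachograms of 2–10 minutes, ECGs of ~2
minutes at 500 Hz, AR simulations of 8192 samples, 1000 random series for
the brute-force oracle comparison and 100 signals for the Parseval check —
sizes at which every documented property is already sharply testable while
the full suite runs in seconds.

## Known limitations

- No Lomb–Scargle or multitaper estimation; spectral analysis requires the
  resampling step.
- No geometric time-domain indices (triangular index, TINN).
- Vendor binary formats (.sdf, .bin, .acq, .abf) and EDF/WFDB are not read;
  inputs are plain text or Polar .hrm.
- The quotient filter's removal semantics (remove the flagged beat itself)
  is one deterministic reading of a rule that is ambiguous in the
  literature; it is documented above and in the API docs.
- The fixed-threshold R-peak detector is deliberately simple; for noisy
  ambulatory ECG a Pan–Tompkins-class detector will outperform it, and
  `edit_peaks` exists precisely because the fixed threshold misses beats.
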