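# hrvkit

Heart rate variability (HRV) analysis for stationary **and** non-stationary
RR-interval series, as a Python library with a matching command-line
interface.

HRV — the beat-to-beat variation of the RR interval (RRi) between successive
heartbeats — is a standard non-invasive window on cardiac autonomic
modulation. Classical indices assume a stationary tachogram, which breaks
down in exactly the situations physiologists care about most (incremental
exercise, tilt test, recovery). `hrvkit` covers the whole pipeline:

- **R-peak detection** on ECG: zero-phase Butterworth band-pass
  (default 5–200 Hz) followed by a derivative zero-crossing rule with a
  fixed amplitude threshold and a 200 ms refractory window, plus
  programmatic peak add/remove editing.
- **Tachogram filtering**: moving average, moving median, and the quotient
  filter, which removes beat *n* whenever RRi_n/RRi_{n±1} ≥ 1.2 or ≤ 0.8
  (two consecutive intervals differing by more than 20%).
- **Time domain**: SDNN, RMSSD, SDSD, Poincaré SD1/SD2, NN50/pNN50, mean
  RRi, mean HR, mean successive difference, with

  SDNN = √( Σⱼ(RRiⱼ − R̄Ri)² / (N−1) ),  RMSSD = √( Σⱼ(RRiⱼ₊₁ − RRiⱼ)² / (N−1) ),

  SD1 = SDSD/√2, SD2 = √(2·SDNN² − SDSD²/2), pNN50 = NN50/N × 100.
- **Frequency domain**: cubic-spline resampling (default 4 Hz), polynomial
  detrending (default linear), PSD by Welch's averaged periodogram
  (segments D = 256 samples, shift S = 128, Hann window, optional zero
  padding; P = ⌊(N−D)/S⌋ + 1 segments) or by a Burg-fitted AR model
  (default order 16); trapezoidal band integration over VLF (0–0.04 Hz),
  LF (0.04–0.15 Hz), HF (0.15–0.4 Hz), with LF/HF and normalized units
  LFnu = LF/(TP−VLF)·100, HFnu = HF/(TP−VLF)·100.
- **Non-stationary analysis**: time-varying indices (every time-domain index
  in sliding windows, default 30 s without overlap) and time–frequency maps
  (per-segment PSDs kept instead of averaged, with a band-power table per
  segment).
- **Synthetic ground truth**: seeded generators for tachograms made of
  LF/HF-band tones plus noise, planted-peak ECGs, stable AR processes and
  exercise-like ramp tachograms — the basis of the test suite.

Supported inputs are plain-text RRi (one interval per line, ms or s),
plain-text ECG (one sample per line), and Polar `.hrm` files; results export
to CSV.

## Worked example

```python
from hrvkit import (TachogramSpec, make_tachogram, time_domain_indices,
                    frequency_analysis)

# 5 min synthetic tachogram: 900 ms mean, one LF tone (0.1 Hz, 30 ms),
# one HF tone (0.25 Hz, 20 ms), 5 ms beat-to-beat noise
spec = TachogramSpec(duration_s=300.0, mean_rri_ms=900.0,
                     tones=((0.1, 30.0, 0.0), (0.25, 20.0, 0.0)),
                     noise_sd_ms=5.0, seed=17)
rri, truth = make_tachogram(spec)

idx = time_domain_indices(rri)
print(f"SDNN = {idx.sdnn:.2f} ms   RMSSD = {idx.rmssd:.2f} ms")
psd, bp = frequency_analysis(rri, method="welch")
print(f"LF = {bp.lf:.1f} ms^2  HF = {bp.hf:.1f} ms^2  LF/HF = {bp.lf_hf:.2f}")
```

prints

```
SDNN = 25.88 ms   RMSSD = 22.80 ms
LF = 459.0 ms^2  HF = 205.2 ms^2  LF/HF = 2.24
```

The measured LF and HF powers sit within ~2% of the analytic tone powers
A²/2 = 450 and 200 ms² recorded in `truth["tone_powers_ms2"]`; the LF tone
is stronger, so LF/HF > 1. The same pipelines are available from the shell:

```sh
hrvkit time-domain rri.txt -o td.csv
hrvkit freq-domain --method welch --segment 256 --overlap 128 rri.txt -o fd.csv
hrvkit time-varying --segment 30 rri.txt -o tv.csv
hrvkit time-frequency --segment 512 --overlap 256 rri.txt -o tf.csv
hrvkit rpeaks --fs 500 --threshold 0.5 ecg.txt -o peaks.csv
```

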