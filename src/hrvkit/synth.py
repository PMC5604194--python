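"""Seeded synthetic ECG and tachogram generators with known ground truth.

These generators produce the controlled inputs used to validate every other
module: tachograms built as sums of LF/HF-band sinusoids plus noise (with
analytic tone powers A^2/2), ECG traces with Gaussian R-waves planted at
known sample positions, stable AR processes of known coefficients, and an
exercise-like ramp tachogram whose mean and variability fall during exercise
and recover afterwards.

The tachogram model evaluates the instantaneous RR value at the accumulated
beat time (amplitude modulation rather than full integral pulse frequency
modulation) -- adequate ground truth for band powers at modulation depths
below ~10% of the mean interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .series import ECGRecord, EvenlySampledSeries, RRiSeries

__all__ = [
    "TachogramSpec",
    "make_tachogram",
    "make_ecg",
    "make_ar_process",
    "make_exercise_tachogram",
]


@dataclass(frozen=True)
class TachogramSpec:
    """Recipe for a synthetic tachogram.

    ``tones`` are (frequency Hz, amplitude ms, phase rad) triples; every
    frequency must stay below 0.5 Hz, the Nyquist limit of the default 4 Hz
    resampling. ``trend`` are polynomial coefficients over time in seconds
    (constant first). ``ectopics`` are (beat index, scale factor) pairs
    applied to the finished series.
    """

    duration_s: float = 300.0
    mean_rri_ms: float = 900.0
    tones: tuple[tuple[float, float, float], ...] = ()
    noise_sd_ms: float = 0.0
    trend: tuple[float, ...] = ()
    ectopics: tuple[tuple[int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.mean_rri_ms <= 0:
            raise ValidationError("duration_s and mean_rri_ms must be positive")
        for freq, _, _ in self.tones:
            if not 0 < freq < 0.5:
                raise ValidationError(
                    f"tone frequency {freq} Hz must lie in (0, 0.5) Hz, below the "
                    "tachogram Nyquist at 4 Hz resampling"
                )


def _rri_at(t: float, spec: TachogramSpec) -> float:
    value = spec.mean_rri_ms
    for freq, amp, phase in spec.tones:
        value += amp * np.sin(2 * np.pi * freq * t + phase)
    for power, coeff in enumerate(spec.trend):
        value += coeff * t**power
    return value


def make_tachogram(spec: TachogramSpec) -> tuple[RRiSeries, dict]:
    """Generate a tachogram beat by beat from a :class:`TachogramSpec`.

    Beat times accumulate iteratively (next beat = previous + current RR
    value / 1000). The ground-truth dict records the analytic tone powers
    (A^2/2, ms^2), the planted ectopic indices and the beat times. The same
    seed always reproduces the same series.
    """
    rng = np.random.default_rng(spec.seed)
    values: list[float] = []
    beat_times: list[float] = []
    t = 0.0
    while True:
        rri_ms = _rri_at(t, spec)
        if spec.noise_sd_ms > 0:
            rri_ms += rng.normal(0.0, spec.noise_sd_ms)
        # a vanishing interval also stalls the beat-time recursion, so treat
        # anything below 1 ms as the spec going non-positive
        if rri_ms < 1.0:
            raise ValidationError(
                f"spec yields a non-positive RR interval ({rri_ms:.1f} ms) at t={t:.1f} s"
            )
        t_next = t + rri_ms / 1000.0
        if t_next > spec.duration_s:
            break
        values.append(rri_ms)
        beat_times.append(t_next)
        t = t_next
    arr = np.asarray(values)
    for idx, scale in spec.ectopics:
        if not 0 <= idx < arr.size:
            raise ValidationError(f"ectopic beat index {idx} outside series of {arr.size}")
        arr[idx] *= scale
        if arr[idx] <= 0:
            raise ValidationError(f"ectopic scale {scale} yields non-positive interval")
    ground_truth = {
        "tone_powers_ms2": {freq: amp**2 / 2.0 for freq, amp, _ in spec.tones},
        "ectopic_indices": [idx for idx, _ in spec.ectopics],
        "beat_times_s": np.asarray(beat_times),
        "mean_rri_ms": spec.mean_rri_ms,
    }
    return RRiSeries(arr, label=f"synthetic tachogram (seed={spec.seed})"), ground_truth


def make_ecg(
    beat_times_s: "list[float] | np.ndarray",
    fs: float,
    r_amplitude: float = 1.0,
    qrs_sigma_s: float = 0.01,
    noise_sd: float = 0.0,
    seed: int = 0,
    pad_s: float = 0.5,
) -> tuple[ECGRecord, np.ndarray]:
    """Synthesize an ECG as Gaussian R-wave bumps on a zero baseline.

    Each beat contributes ``r_amplitude * exp(-(t - t_b)^2 / (2 sigma^2))``;
    seeded Gaussian noise is added on top. Returns the record and the planted
    peak indices (``round(t_b * fs)``). Beats closer together than 3 sigma
    would merge their bumps and are rejected.
    """
    beat_times = np.sort(np.asarray(beat_times_s, dtype=float))
    if beat_times.size == 0:
        raise ValidationError("need at least one beat time")
    if qrs_sigma_s <= 0:
        raise ValidationError("qrs_sigma_s must be positive")
    if beat_times.size > 1 and np.min(np.diff(beat_times)) < 3 * qrs_sigma_s:
        raise ValidationError(
            f"beats spaced closer than 3*sigma = {3 * qrs_sigma_s:.3f} s would overlap"
        )
    duration = beat_times[-1] + pad_s
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    samples = np.zeros(n)
    for tb in beat_times:
        lo = max(0, int((tb - 5 * qrs_sigma_s) * fs))
        hi = min(n, int((tb + 5 * qrs_sigma_s) * fs) + 1)
        samples[lo:hi] += r_amplitude * np.exp(-((t[lo:hi] - tb) ** 2) / (2 * qrs_sigma_s**2))
    if noise_sd > 0:
        samples += np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    planted = np.round(beat_times * fs).astype(np.int64)
    return ECGRecord(samples, fs=fs), planted


def make_ar_process(
    coeffs: "list[float] | np.ndarray",
    noise_sd: float = 1.0,
    n: int = 1024,
    seed: int = 0,
    fs: float = 1.0,
) -> EvenlySampledSeries:
    """Simulate a stationary AR process ``x_t = sum_k coeffs[k] x_{t-k} + e_t``.

    Stability is checked via the companion-matrix spectral radius; the first
    500 burn-in samples are discarded. Empty ``coeffs`` gives white noise.
    """
    phi = np.asarray(coeffs, dtype=float)
    p = phi.size
    if p:
        companion = np.zeros((p, p))
        companion[0] = phi
        if p > 1:
            companion[1:, :-1] = np.eye(p - 1)
        radius = np.max(np.abs(np.linalg.eigvals(companion)))
        if radius >= 1.0 - 1e-12:
            raise ValidationError(
                f"AR coefficients {phi.tolist()} are not stationary (spectral radius {radius:.4f})"
            )
    burn_in = 500
    rng = np.random.default_rng(seed)
    e = rng.normal(0.0, noise_sd, size=n + burn_in)
    x = np.zeros(n + burn_in)
    for t in range(n + burn_in):
        acc = e[t]
        for k in range(min(p, t)):
            acc += phi[k] * x[t - 1 - k]
        x[t] = acc
    return EvenlySampledSeries(x[burn_in:], fs=fs)


def make_exercise_tachogram(
    ramp_s: float = 300.0,
    recovery_s: float = 300.0,
    rest_rri_ms: float = 900.0,
    peak_exercise_rri_ms: float = 350.0,
    recovery_rri_ms: float = 600.0,
    rest_amp_ms: float = 50.0,
    peak_amp_ms: float = 2.0,
    recovery_amp_ms: float = 30.0,
    hf_freq: float = 0.25,
    noise_frac: float = 0.05,
    seed: int = 0,
) -> tuple[RRiSeries, dict]:
    """An exercise-like non-stationary tachogram: linear ramp, then recovery.

    During the ramp the mean RR interval falls linearly from rest to peak
    exercise and the HF oscillation amplitude decays geometrically; during
    recovery both rise back exponentially (time constant = recovery/3). Noise
    is Gaussian with standard deviation ``noise_frac`` of the local
    oscillation amplitude, so variability genuinely shrinks with exercise
    intensity. The ground truth records the phase boundary and the amplitude
    envelope for monotonicity checks.
    """
    rng = np.random.default_rng(seed)
    total = ramp_s + recovery_s
    tau = recovery_s / 3.0

    def mean_at(t: float) -> float:
        if t <= ramp_s:
            return rest_rri_ms + (peak_exercise_rri_ms - rest_rri_ms) * t / ramp_s
        dt = t - ramp_s
        return recovery_rri_ms + (peak_exercise_rri_ms - recovery_rri_ms) * np.exp(-dt / tau)

    def amp_at(t: float) -> float:
        if t <= ramp_s:
            return rest_amp_ms * (peak_amp_ms / rest_amp_ms) ** (t / ramp_s)
        dt = t - ramp_s
        return recovery_amp_ms + (peak_amp_ms - recovery_amp_ms) * np.exp(-dt / tau)

    values: list[float] = []
    beat_times: list[float] = []
    t = 0.0
    while True:
        amp = amp_at(t)
        rri_ms = (
            mean_at(t)
            + amp * np.sin(2 * np.pi * hf_freq * t)
            + rng.normal(0.0, noise_frac * amp)
        )
        if rri_ms < 1.0:
            raise ValidationError("exercise spec produced a non-positive interval")
        t_next = t + rri_ms / 1000.0
        if t_next > total:
            break
        values.append(rri_ms)
        beat_times.append(t_next)
        t = t_next
    ground_truth = {
        "ramp_end_s": ramp_s,
        "total_s": total,
        "amp_at": amp_at,
        "mean_at": mean_at,
        "beat_times_s": np.asarray(beat_times),
    }
    return RRiSeries(np.asarray(values), label=f"synthetic exercise ramp (seed={seed})"), ground_truth
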