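"""R-peak detection on ECG by derivative zero-crossing plus a fixed threshold.

The detector band-pass filters the ECG (zero-phase Butterworth, default
passband 5-200 Hz) to suppress baseline wander and high-frequency noise,
marks candidate peaks where the first difference of the filtered signal turns
from positive to non-positive, and keeps a candidate only when the *raw* ECG
sample there exceeds a user-supplied fixed threshold. A 200 ms refractory
window (the physiological minimum RR interval) suppresses double detections
on a single QRS complex. Detection errors are fixed programmatically with
:func:`edit_peaks`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import InsufficientDataError, ValidationError
from .series import ECGRecord, RRiSeries

__all__ = [
    "PeakAnnotation",
    "bandpass_ecg",
    "detect_rpeaks",
    "edit_peaks",
    "peaks_to_rri",
    "REFRACTORY_S",
]

#: Minimum physiological spacing between two R-peaks, seconds.
REFRACTORY_S = 0.2


@dataclass(frozen=True)
class PeakAnnotation:
    """Detected (or edited) R-peak positions as sample indices into an ECG."""

    peak_indices: np.ndarray
    fs: float
    n_samples: int
    threshold_used: float = float("nan")
    passband_used: tuple[float, float] = (float("nan"), float("nan"))

    def __post_init__(self) -> None:
        idx = np.asarray(self.peak_indices, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_samples):
            raise ValidationError("peak indices must lie within [0, n_samples)")
        if idx.size > 1 and np.any(np.diff(idx) <= 0):
            raise ValidationError("peak indices must be strictly increasing")
        object.__setattr__(self, "peak_indices", idx)

    @property
    def peak_times(self) -> np.ndarray:
        """Peak times in seconds from the start of the record."""
        return self.peak_indices / self.fs

    def __len__(self) -> int:
        return self.peak_indices.size


def bandpass_ecg(ecg: ECGRecord, low: float = 5.0, high: float = 200.0, order: int = 4) -> ECGRecord:
    """Zero-phase Butterworth band-pass filter of an ECG record.

    Forward-backward application (``sosfiltfilt``) has no group delay, so
    R-peak latencies are preserved. ``high`` must be below the Nyquist
    frequency; for low sampling rates the 200 Hz default is infeasible and
    must be lowered explicitly rather than silently clipped.
    """
    if not 0 < low < high:
        raise ValidationError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= ecg.fs / 2:
        raise ValidationError(
            f"upper passband edge {high} Hz must be below the Nyquist frequency "
            f"{ecg.fs / 2} Hz; lower the 'high' cutoff for this {ecg.fs} Hz recording"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=ecg.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, ecg.samples)
    return ECGRecord(filtered, fs=ecg.fs, start_time=ecg.start_time)


def detect_rpeaks(
    ecg_raw: ECGRecord,
    threshold: float,
    low: float = 5.0,
    high: float = 200.0,
    order: int = 4,
) -> PeakAnnotation:
    """Detect R-peaks by derivative zero-crossing and a fixed amplitude threshold.

    A sample ``i`` is a candidate when the first difference of the band-passed
    signal goes from positive to non-positive at ``i`` (a local maximum of the
    filtered trace). The candidate is accepted when the raw ECG at ``i``
    exceeds ``threshold``. Within any 200 ms refractory window only the
    largest raw-amplitude candidate is kept. An empty annotation (no peak
    above threshold) is a valid result, not an error.
    """
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    if len(ecg_raw) < 3 * order:
        raise InsufficientDataError(f"ECG too short to filter: need at least {3 * order} samples")
    filtered = bandpass_ecg(ecg_raw, low=low, high=high, order=order).samples
    d = np.diff(filtered)
    # zero-crossing of the derivative: d[i-1] > 0 and d[i] <= 0 -> local max at i
    cross = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
    raw = ecg_raw.samples
    candidates = cross[raw[cross] > threshold]

    refractory = max(1, int(round(REFRACTORY_S * ecg_raw.fs)))
    kept: list[int] = []
    # greedy by descending raw amplitude: the largest candidate in any
    # refractory-sized neighbourhood wins
    for i in candidates[np.argsort(raw[candidates], kind="stable")[::-1]]:
        if all(abs(int(i) - j) >= refractory for j in kept):
            kept.append(int(i))
    return PeakAnnotation(
        np.sort(np.asarray(kept, dtype=np.int64)),
        fs=ecg_raw.fs,
        n_samples=len(ecg_raw),
        threshold_used=float(threshold),
        passband_used=(float(low), float(high)),
    )


def edit_peaks(
    ann: PeakAnnotation,
    add: "list[int] | np.ndarray" = (),
    remove: "list[int] | np.ndarray" = (),
) -> PeakAnnotation:
    """Manually add and/or remove peaks from an annotation.

    Manual additions override the algorithm: the refractory rule is *not*
    re-applied to them. Removing an index that is not present is a warning,
    not an error; adding an out-of-bounds index is rejected.
    """
    add = np.asarray(add, dtype=np.int64).ravel()
    remove = np.asarray(remove, dtype=np.int64).ravel()
    if add.size and (add.min() < 0 or add.max() >= ann.n_samples):
        raise ValidationError(f"added peak indices must lie within [0, {ann.n_samples})")
    current = set(ann.peak_indices.tolist())
    for r in remove.tolist():
        if r in current:
            current.discard(r)
        else:
            warnings.warn(f"peak index {r} not present; nothing removed", stacklevel=2)
    current.update(add.tolist())
    return PeakAnnotation(
        np.asarray(sorted(current), dtype=np.int64),
        fs=ann.fs,
        n_samples=ann.n_samples,
        threshold_used=ann.threshold_used,
        passband_used=ann.passband_used,
    )


def peaks_to_rri(ann: PeakAnnotation) -> RRiSeries:
    """Convert peak positions to the RR-interval series (ms) between them."""
    if len(ann) < 2:
        raise InsufficientDataError("need at least two peaks to form RR intervals")
    rri_ms = np.diff(ann.peak_indices) / ann.fs * 1000.0
    return RRiSeries(rri_ms, label="derived from R-peak annotation")
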