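"""Non-stationary HRV: time-varying indices and time-frequency band-power maps.

Time-varying analysis slides a window of fixed duration (default 30 s, no
overlap) over the cumulative beat time axis and computes every stationary
time-domain index inside each window; it is the tool of choice for tracking
RMSSD through exercise or a tilt test. Windows count *seconds*, an interval
belongs to the window containing its end time, and a trailing incomplete
window is dropped.

Time-frequency analysis segments the evenly *resampled* tachogram exactly as
Welch's method would (segment and overlap in samples) but keeps each
sub-segment's periodogram instead of averaging, yielding a time x frequency
PSD matrix plus a per-segment band-power table; averaging the rows
reproduces the Welch estimate of identical configuration. Sub-segment PSDs
may also be Burg AR estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InsufficientDataError, ValidationError
from .freq_domain import (
    ARConfig,
    DEFAULT_BAND_EDGES,
    PSDEstimate,
    WelchConfig,
    band_powers,
    burg_psd,
)
from .preprocess import detrend_polynomial, interpolate_resample
from .series import EvenlySampledSeries, RRiSeries
from .time_domain import TimeDomainIndices, time_domain_indices

__all__ = ["TimeVaryingResult", "TimeFrequencyMap", "time_varying_indices", "time_frequency_map"]

_TIME_TOL = 1e-9


@dataclass(frozen=True)
class TimeVaryingResult:
    """Per-window time-domain indices of a sliding-window analysis."""

    segment_starts: np.ndarray   # s
    segment_ends: np.ndarray     # s
    indices: tuple[TimeDomainIndices, ...]
    n_beats_per_segment: np.ndarray
    segment_len_s: float
    overlap_s: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for start, end, idx, nb in zip(
            self.segment_starts, self.segment_ends, self.indices, self.n_beats_per_segment
        ):
            row = {"segment_start_s": float(start), "segment_end_s": float(end)}
            row.update(idx.as_dict())
            row["n_intervals"] = int(nb)
            rows.append(row)
        return pd.DataFrame.from_records(rows)

    def __len__(self) -> int:
        return self.segment_starts.size


@dataclass(frozen=True)
class TimeFrequencyMap:
    """Per-segment PSDs (rows) over a common frequency grid, plus band powers."""

    times: np.ndarray            # s, segment centers
    freqs: np.ndarray            # Hz
    power: np.ndarray            # (n_segments, n_freqs) ms^2/Hz
    band_power_table: pd.DataFrame
    method: str
    config: dict

    def __post_init__(self) -> None:
        if self.power.shape != (self.times.size, self.freqs.size):
            raise ValidationError("power matrix shape must be (n_segments, n_freqs)")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("segment times must be strictly increasing")

    def mean_psd(self) -> PSDEstimate:
        """Average of all rows — equals the Welch estimate of the same config."""
        return PSDEstimate(self.freqs, self.power.mean(axis=0), method=self.method,
                           fs=self.config["fs"])

    def __len__(self) -> int:
        return self.times.size


def _window_starts(duration: float, segment_len_s: float, overlap_s: float,
                   t0: float = 0.0) -> np.ndarray:
    step = segment_len_s - overlap_s
    n = int(np.floor((duration - segment_len_s) / step + _TIME_TOL)) + 1
    return t0 + step * np.arange(n)


def time_varying_indices(
    rri: RRiSeries,
    segment_len_s: float = 30.0,
    overlap_s: float = 0.0,
) -> TimeVaryingResult:
    """Time-domain indices in sliding windows over the beat-time axis.

    Windows start at ``k * (segment_len_s - overlap_s)`` seconds; an interval
    belongs to the window containing its end time (half-open ``(start, end]``
    membership so window boundaries are unambiguous). Windows holding fewer
    than two intervals yield NaN-marked indices.
    """
    if not 0 <= overlap_s < segment_len_s:
        raise ValidationError(
            f"need 0 <= overlap < segment length, got overlap={overlap_s}, segment={segment_len_s}"
        )
    duration = rri.duration_s
    if duration + _TIME_TOL < segment_len_s:
        raise InsufficientDataError(
            f"record lasts {duration:.3f} s but one segment needs {segment_len_s} s"
        )
    onsets = rri.onset_times
    starts = _window_starts(duration, segment_len_s, overlap_s)
    ends = starts + segment_len_s
    indices: list[TimeDomainIndices] = []
    n_beats: list[int] = []
    for start, end in zip(starts, ends):
        mask = (onsets > start + _TIME_TOL) & (onsets <= end + _TIME_TOL)
        chunk = rri.values[mask]
        n_beats.append(int(chunk.size))
        if chunk.size >= 2:
            indices.append(time_domain_indices(RRiSeries(chunk)))
        else:
            nan = float("nan")
            indices.append(TimeDomainIndices(
                mean_rri=nan, mean_hr=nan, mean_succ_diff=nan, sdnn=nan, rmssd=nan,
                sdsd=nan, sd1=nan, sd2=nan, nn50=nan, pnn50=nan,
                n_intervals=int(chunk.size),
            ))
    return TimeVaryingResult(
        segment_starts=starts,
        segment_ends=ends,
        indices=tuple(indices),
        n_beats_per_segment=np.asarray(n_beats),
        segment_len_s=float(segment_len_s),
        overlap_s=float(overlap_s),
    )


def time_frequency_map(
    rri: RRiSeries,
    method: str = "welch_segment",
    fs: float = 4.0,
    segment_len: int = 256,
    overlap: int = 128,
    window: str = "hann",
    order: int = 16,
    padded_len: int | None = None,
    band_edges: tuple[float, float, float, float] = DEFAULT_BAND_EDGES,
    detrend_degree: int | None = 1,
    kaiser_beta: float = 8.6,
) -> TimeFrequencyMap:
    """Short-time spectral decomposition of the tachogram with band powers.

    The tachogram is resampled at ``fs`` and globally detrended, then split
    into segments of ``segment_len`` samples overlapping by ``overlap``
    samples. ``method="welch_segment"`` computes one mean-removed, windowed
    periodogram per segment (no averaging); ``method="ar"`` fits a Burg AR
    model of the given order per segment. Band powers are integrated per
    row, and segment times are the segment centers on the resampled grid.
    """
    if method not in ("welch_segment", "ar"):
        raise ValidationError(f"method must be 'welch_segment' or 'ar', got {method!r}")
    if not 0 <= overlap < segment_len:
        raise ValidationError(
            f"need 0 <= overlap < segment_len, got overlap={overlap}, segment_len={segment_len}"
        )
    even = interpolate_resample(rri, fs=fs)
    if detrend_degree is not None:
        even = detrend_polynomial(even, degree=detrend_degree)
    n = len(even)
    if n < segment_len:
        raise InsufficientDataError(
            f"resampled series has {n} samples but one segment needs {segment_len}"
        )
    shift = segment_len - overlap
    nfft = padded_len or segment_len
    n_segments = (n - segment_len) // shift + 1
    start_idx = shift * np.arange(n_segments)
    times = even.t0 + (start_idx + (segment_len - 1) / 2.0) / fs

    wcfg = WelchConfig(segment_len=segment_len, shift=shift, window=window,
                       kaiser_beta=kaiser_beta, padded_len=nfft)
    if method == "welch_segment":
        freqs, _, sxx = sps.spectrogram(
            even.values,
            fs=fs,
            window=wcfg.scipy_window,
            nperseg=segment_len,
            noverlap=overlap,
            nfft=nfft,
            detrend="constant",
            scaling="density",
            mode="psd",
        )
        power = sxx.T[:n_segments]
        config = {"fs": fs, "segment_len": segment_len, "overlap": overlap,
                  "window": window, "padded_len": nfft, "detrend_degree": detrend_degree}
    else:
        acfg = ARConfig(order=order, padded_len=nfft)
        rows = []
        freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
        for s in start_idx:
            chunk = even.values[s: s + segment_len]
            chunk_series = EvenlySampledSeries(chunk - chunk.mean(), fs=fs,
                                               t0=even.t0 + s / fs)
            rows.append(burg_psd(chunk_series, acfg).power)
        power = np.vstack(rows)
        config = {"fs": fs, "segment_len": segment_len, "overlap": overlap,
                  "order": order, "padded_len": nfft, "detrend_degree": detrend_degree}

    records = []
    for t, row, s in zip(times, power, start_idx):
        psd = PSDEstimate(freqs, row, method="welch" if method == "welch_segment" else "ar", fs=fs)
        bp = band_powers(psd, edges=band_edges)
        rec = {"segment_start_s": float(even.t0 + s / fs),
               "segment_end_s": float(even.t0 + (s + segment_len - 1) / fs),
               "segment_center_s": float(t)}
        rec.update(bp.as_dict())
        records.append(rec)
    table = pd.DataFrame.from_records(records)
    return TimeFrequencyMap(times=times, freqs=freqs, power=power,
                            band_power_table=table,
                            method="welch_segment" if method == "welch_segment" else "ar",
                            config=config)
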