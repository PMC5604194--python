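"""Core data containers: RR-interval series, ECG records, evenly resampled series.

Unit conventions used throughout the package: RR intervals are milliseconds,
time axes are seconds, sampling frequencies are hertz. An interval's time
stamp is the time at which it *ends* (cumulative sum of intervals), so the
first interval of a record ends at ``values[0] / 1000`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ValidationError

__all__ = ["RRiSeries", "ECGRecord", "EvenlySampledSeries"]


@dataclass(frozen=True)
class RRiSeries:
    """An ordered sequence of RR intervals in milliseconds (the tachogram).

    Parameters
    ----------
    values : array-like of float
        RR intervals in ms, in beat order. Must be strictly positive and finite.
    label : str, optional
        Free-text provenance (file name, recording notes).
    """

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValidationError("RRiSeries requires a 1-D sequence of at least one interval")
        if not np.all(np.isfinite(values)):
            raise ValidationError("RR intervals must be finite")
        if np.any(values <= 0):
            bad = int(np.argmax(values <= 0))
            raise ValidationError(f"RR intervals must be strictly positive (index {bad}: {values[bad]!r})")
        object.__setattr__(self, "values", values)

    @property
    def onset_times(self) -> np.ndarray:
        """Cumulative end time of each interval, in seconds."""
        return np.cumsum(self.values) / 1000.0

    @property
    def duration_s(self) -> float:
        """Total record duration in seconds (end of last interval)."""
        return float(np.sum(self.values)) / 1000.0

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ECGRecord:
    """An evenly sampled single-lead ECG voltage trace.

    Parameters
    ----------
    samples : array-like of float
        Voltage samples, arbitrary units.
    fs : float
        Sampling frequency in Hz, > 0.
    start_time : float
        Time of the first sample, seconds.
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if not self.fs > 0:
            raise ValidationError(f"sampling frequency must be > 0, got {self.fs!r}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValidationError("ECGRecord requires at least two samples")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("ECG samples must be finite")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs

    @property
    def duration_s(self) -> float:
        return (self.samples.size - 1) / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class EvenlySampledSeries:
    """A tachogram resampled onto an even time grid (step ``1/fs`` seconds).

    ``values`` keep the RR-interval amplitude in ms; ``t0`` is the time of the
    first grid point in seconds.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not self.fs > 0:
            raise ValidationError(f"resampling frequency must be > 0, got {self.fs!r}")
        if values.ndim != 1 or values.size < 2:
            raise InsufficientDataError("EvenlySampledSeries requires at least two grid points")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    def __len__(self) -> int:
        return self.values.size
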