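"""Tachogram preprocessing: artifact filters, detrending, and resampling.

Three artifact filters are provided. The moving average and moving median
smooth the series in place (centered windows, truncated at the edges so the
length is preserved). The quotient filter *removes* beats: a beat is dropped
when its ratio with either neighbour leaves the 0.8-1.2 band, i.e. when two
consecutive intervals differ by more than 20%. All flags are computed on the
original series and the removals applied in a single pass.

For spectral analysis the irregularly sampled tachogram is cubic-spline
interpolated and resampled onto an even grid (default 4 Hz), after which a
least-squares polynomial trend (default linear) can be subtracted.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import InsufficientDataError, ValidationError
from .series import EvenlySampledSeries, RRiSeries

__all__ = [
    "moving_average_filter",
    "moving_median_filter",
    "quotient_filter",
    "detrend_polynomial",
    "interpolate_resample",
]


def moving_average_filter(rri: RRiSeries, order: int) -> RRiSeries:
    """Centered moving average of order ``N``; edge windows are truncated.

    Value ``j`` of the output is the mean of the up-to-``N`` input values in
    the window centered on ``j``, averaging only over the points that exist
    near the edges, so the output has the same length as the input.
    """
    n = len(rri)
    if order < 1:
        raise ValidationError(f"filter order must be >= 1, got {order}")
    if order > n:
        raise ValidationError(f"filter order {order} exceeds series length {n}")
    kernel = np.ones(order)
    num = np.convolve(rri.values, kernel, mode="same")
    den = np.convolve(np.ones(n), kernel, mode="same")
    return RRiSeries(num / den, label=rri.label)


def moving_median_filter(rri: RRiSeries, order: int) -> RRiSeries:
    """Centered moving median of odd order ``N``; edge windows are truncated."""
    n = len(rri)
    if order < 1 or order % 2 == 0:
        raise ValidationError(f"median filter order must be an odd number >= 1, got {order}")
    if order > n:
        raise ValidationError(f"filter order {order} exceeds series length {n}")
    half = order // 2
    out = np.array([np.median(rri.values[max(0, j - half): j + half + 1]) for j in range(n)])
    return RRiSeries(out, label=rri.label)


def quotient_filter(rri: RRiSeries) -> tuple[RRiSeries, np.ndarray]:
    """Remove ectopic beats whose ratio with a neighbour leaves [0.8, 1.2].

    Beat ``n`` is flagged when ``RRi_n / RRi_{n-1}`` or ``RRi_n / RRi_{n+1}``
    is >= 1.2 or <= 0.8 (thresholds inclusive); the endpoints are compared
    with their single neighbour. Flags are evaluated on the original series
    and all flagged beats removed at once -- a single deterministic pass, no
    iteration.

    Returns
    -------
    (filtered, removed_indices)
        The filtered series may be empty, in which case ``filtered`` is
        ``None`` and every index is listed in ``removed_indices``.
    """
    v = rri.values
    n = v.size
    if n < 2:
        raise InsufficientDataError("quotient filter needs at least two intervals")
    with np.errstate(divide="ignore"):
        prev_ratio = v[1:] / v[:-1]          # beat n vs its predecessor, n >= 1
        next_ratio = v[:-1] / v[1:]          # beat n vs its successor, n <= N-2
    flagged = np.zeros(n, dtype=bool)
    bad_prev = (prev_ratio >= 1.2) | (prev_ratio <= 0.8)
    bad_next = (next_ratio >= 1.2) | (next_ratio <= 0.8)
    flagged[1:] |= bad_prev
    flagged[:-1] |= bad_next
    removed = np.flatnonzero(flagged)
    kept = v[~flagged]
    filtered = RRiSeries(kept, label=rri.label) if kept.size else None
    return filtered, removed


def detrend_polynomial(series: EvenlySampledSeries, degree: int = 1) -> EvenlySampledSeries:
    """Subtract a least-squares polynomial trend of the given degree.

    The polynomial is fitted to the series values against time; degrees from
    1 (linear, the default) up to ``n - 1`` are accepted.
    """
    n = len(series)
    if not 1 <= degree <= n - 1:
        raise ValidationError(f"polynomial degree must be in [1, {n - 1}], got {degree}")
    t = series.times
    coeffs = np.polynomial.polynomial.polyfit(t - t[0], series.values, degree)
    trend = np.polynomial.polynomial.polyval(t - t[0], coeffs)
    return EvenlySampledSeries(series.values - trend, fs=series.fs, t0=series.t0)


def interpolate_resample(rri: RRiSeries, fs: float = 4.0) -> EvenlySampledSeries:
    """Cubic-spline interpolate the tachogram and resample at ``fs`` Hz.

    RR-interval values are interpolated against their cumulative end times
    and evaluated on the even grid spanning the first to the last beat time,
    with both endpoints included (``floor(span * fs) + 1`` grid points).
    """
    if not fs > 0:
        raise ValidationError(f"resampling frequency must be > 0, got {fs!r}")
    if len(rri) < 4:
        raise InsufficientDataError("cubic-spline resampling needs at least 4 beats")
    t = rri.onset_times
    spline = CubicSpline(t, rri.values)
    n_points = int(np.floor((t[-1] - t[0]) * fs + 1e-9)) + 1
    grid = t[0] + np.arange(n_points) / fs
    return EvenlySampledSeries(spline(grid), fs=fs, t0=float(t[0]))
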