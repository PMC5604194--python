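"""Stationary time-domain HRV indices.

With :math:`RRi_j` the j-th of N intervals (ms):

.. math::

    SDNN  &= \\sqrt{\\tfrac{1}{N-1} \\sum_{j=1}^{N} (RRi_j - \\overline{RRi})^2} \\\\
    RMSSD &= \\sqrt{\\tfrac{1}{N-1} \\sum_{j=1}^{N-1} (RRi_{j+1} - RRi_j)^2} \\\\
    SD1   &= SDSD / \\sqrt{2} \\qquad
    SD2    = \\sqrt{2\\,SDNN^2 - \\tfrac{1}{2} SDSD^2} \\\\
    pNN50 &= \\tfrac{NN50}{N} \\times 100

where SDSD is the centered standard deviation of the N-1 successive
differences with denominator N-1, and NN50 counts successive differences
strictly greater than 50 ms. Note the pNN50 denominator here is the *total*
interval count N; the conventional N-1 variant is available via
``pnn50_denominator="n-1"``. SD1/SD2 are the Poincare-plot dispersions
across and along the identity line and satisfy
:math:`SD1^2 + SD2^2 = 2\\,SDNN^2`.

Mean HR is by default the mean of the instantaneous heart rate
:math:`60000 / RRi_j` over beats; the alternative convention
``60000 / \\overline{RRi}`` is available via ``hr_from="mean_rri"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .series import RRiSeries

__all__ = [
    "TimeDomainIndices",
    "sdnn",
    "rmssd",
    "sdsd",
    "poincare_sd",
    "nn50_pnn50",
    "mean_indices",
    "time_domain_indices",
]


@dataclass(frozen=True)
class TimeDomainIndices:
    """One row of stationary time-domain HRV indices."""

    mean_rri: float      # ms
    mean_hr: float       # bpm
    mean_succ_diff: float  # ms, signed
    sdnn: float          # ms
    rmssd: float         # ms
    sdsd: float          # ms
    sd1: float           # ms
    sd2: float           # ms
    nn50: float          # count (float so it can be NaN-marked)
    pnn50: float         # %
    n_intervals: int

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _values(rri: RRiSeries | np.ndarray) -> np.ndarray:
    return rri.values if isinstance(rri, RRiSeries) else np.asarray(rri, dtype=float)


def sdnn(rri: RRiSeries) -> float:
    """Standard deviation of the RR intervals (N-1 denominator), ms."""
    v = _values(rri)
    if v.size < 2:
        raise InsufficientDataError("SDNN needs at least two intervals")
    return float(np.std(v, ddof=1))


def rmssd(rri: RRiSeries) -> float:
    """Root mean square of the N-1 successive differences, ms."""
    v = _values(rri)
    if v.size < 2:
        raise InsufficientDataError("RMSSD needs at least two intervals")
    d = np.diff(v)
    return float(math.sqrt(np.sum(d * d) / (v.size - 1)))


def sdsd(rri: RRiSeries) -> float:
    """Centered standard deviation of successive differences (denominator N-1), ms."""
    v = _values(rri)
    if v.size < 2:
        raise InsufficientDataError("SDSD needs at least two intervals")
    d = np.diff(v)
    return float(np.sqrt(np.mean((d - d.mean()) ** 2)))


def poincare_sd(rri: RRiSeries) -> tuple[float, float]:
    """Poincare-plot dispersions (SD1, SD2) in ms.

    SD1 = SDSD/sqrt(2) captures short-term (beat-to-beat) variability; SD2 =
    sqrt(2*SDNN^2 - SDSD^2/2) the long-term variability along the identity
    line. A negative radicand within numerical tolerance is clamped to 0.
    """
    v = _values(rri)
    if v.size < 3:
        raise InsufficientDataError("Poincare SD1/SD2 need at least three intervals")
    s = sdsd(rri)
    sd2_sq = 2.0 * sdnn(rri) ** 2 - 0.5 * s**2
    if sd2_sq < 0:
        sd2_sq = 0.0
    return s / math.sqrt(2.0), math.sqrt(sd2_sq)


def nn50_pnn50(rri: RRiSeries, denominator: str = "n") -> tuple[int, float]:
    """Count (NN50) and percentage (pNN50) of successive differences > 50 ms.

    The inequality is strict. ``denominator="n"`` (default) divides by the
    total interval count N; ``"n-1"`` gives the conventional variant dividing
    by the number of differences.
    """
    if denominator not in ("n", "n-1"):
        raise ValidationError(f"denominator must be 'n' or 'n-1', got {denominator!r}")
    v = _values(rri)
    if v.size < 2:
        raise InsufficientDataError("pNN50 needs at least two intervals")
    count = int(np.count_nonzero(np.abs(np.diff(v)) > 50.0))
    den = v.size if denominator == "n" else v.size - 1
    return count, 100.0 * count / den


def mean_indices(rri: RRiSeries, hr_from: str = "instantaneous") -> tuple[float, float, float]:
    """Mean RRi (ms), mean HR (bpm) and mean signed successive difference (ms).

    ``hr_from="instantaneous"`` averages the per-beat heart rate 60000/RRi_j;
    ``hr_from="mean_rri"`` reports 60000 divided by the mean interval.
    """
    if hr_from not in ("instantaneous", "mean_rri"):
        raise ValidationError(f"hr_from must be 'instantaneous' or 'mean_rri', got {hr_from!r}")
    v = _values(rri)
    mean_rri = float(np.mean(v))
    mean_hr = float(np.mean(60000.0 / v)) if hr_from == "instantaneous" else 60000.0 / mean_rri
    mean_sd = float(np.mean(np.diff(v))) if v.size >= 2 else float("nan")
    return mean_rri, mean_hr, mean_sd


def time_domain_indices(
    rri: RRiSeries,
    hr_from: str = "instantaneous",
    pnn50_denominator: str = "n",
) -> TimeDomainIndices:
    """All stationary time-domain indices of a tachogram in one record."""
    v = _values(rri)
    mean_rri, mean_hr, mean_sd = mean_indices(rri, hr_from=hr_from)
    if v.size >= 2:
        _sdnn, _rmssd, _sdsd = sdnn(rri), rmssd(rri), sdsd(rri)
        _nn50, _pnn50 = nn50_pnn50(rri, denominator=pnn50_denominator)
    else:
        _sdnn = _rmssd = _sdsd = float("nan")
        _nn50 = _pnn50 = float("nan")
    if v.size >= 3:
        _sd1, _sd2 = poincare_sd(rri)
    else:
        _sd1 = _sd2 = float("nan")
    return TimeDomainIndices(
        mean_rri=mean_rri,
        mean_hr=mean_hr,
        mean_succ_diff=mean_sd,
        sdnn=_sdnn,
        rmssd=_rmssd,
        sdsd=_sdsd,
        sd1=_sd1,
        sd2=_sd2,
        nn50=float(_nn50),
        pnn50=_pnn50,
        n_intervals=int(v.size),
    )
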