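"""Frequency-domain HRV: Welch and Burg (AR) PSD estimation and band powers.

The tachogram is cubic-spline resampled (default 4 Hz), polynomial-detrended
(default linear), and its one-sided power spectral density estimated either
by Welch's averaged periodogram,

.. math:: PSD(f) = \\frac{1}{P} \\sum_{p=1}^{P} PSD^{(p)}(f), \\qquad
          P = \\left\\lfloor \\frac{N - D}{S} \\right\\rfloor + 1,

with segment length D (default 256 samples), shift S between adjacent
segments (default 128, i.e. 50% overlap), a taper window (default Hann) and
optional zero padding; or by fitting an autoregressive model of order p
(default 16) with Burg's method, minimising the summed forward and backward
prediction error, and evaluating the model's frequency response,

.. math:: PSD(f) = \\frac{2\\,\\sigma^2}{f_s\\,|1 + \\sum_{k=1}^{p} a_k
          e^{-i 2 \\pi f k / f_s}|^2}.

Band powers (ms^2) are trapezoidal integrals of the density over VLF
(0-0.04 Hz), LF (0.04-0.15 Hz), HF (0.15-0.4 Hz) and TP (0-0.4 Hz) by
default, with the density linearly interpolated at the exact band edges so
contiguous bands tile the axis without gap or overlap. Normalised units
divide by (TP - VLF):

.. math:: LF_{n.u.} = \\frac{LF}{TP - VLF} \\times 100, \\qquad
          HF_{n.u.} = \\frac{HF}{TP - VLF} \\times 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, ValidationError
from .preprocess import detrend_polynomial, interpolate_resample
from .series import EvenlySampledSeries, RRiSeries

__all__ = [
    "WelchConfig",
    "ARConfig",
    "PSDEstimate",
    "BandPowers",
    "DEFAULT_BAND_EDGES",
    "welch_psd",
    "burg_psd",
    "burg_coefficients",
    "band_powers",
    "frequency_analysis",
]

#: (vlf_lo, vlf_hi, lf_hi, hf_hi) in Hz — contiguous VLF/LF/HF bands.
DEFAULT_BAND_EDGES: tuple[float, float, float, float] = (0.0, 0.04, 0.15, 0.4)

_WINDOW_ALIASES = {
    "hann": "hann",
    "hanning": "hann",
    "hamming": "hamming",
    "kaiser": "kaiser",
    "blackman": "blackman",
    "triangular": "triang",
    "triang": "triang",
    # not in the GUI's window list but needed for Parseval-style checks
    "rectangular": "boxcar",
    "boxcar": "boxcar",
}


@dataclass(frozen=True)
class WelchConfig:
    """Segmentation, window and padding settings for Welch's method."""

    segment_len: int = 256
    shift: int = 128
    window: str = "hann"
    kaiser_beta: float = 8.6
    padded_len: int | None = None

    def __post_init__(self) -> None:
        pad = self.segment_len if self.padded_len is None else self.padded_len
        if not 1 <= self.shift <= self.segment_len <= pad:
            raise ValidationError(
                f"need 1 <= shift <= segment_len <= padded_len, got "
                f"shift={self.shift}, segment_len={self.segment_len}, padded_len={pad}"
            )
        if self.window not in _WINDOW_ALIASES:
            raise ValidationError(
                f"unknown window {self.window!r}; choose from {sorted(set(_WINDOW_ALIASES))}"
            )
        object.__setattr__(self, "padded_len", pad)

    @property
    def scipy_window(self) -> "str | tuple":
        name = _WINDOW_ALIASES[self.window]
        return (name, self.kaiser_beta) if name == "kaiser" else name

    @property
    def noverlap(self) -> int:
        return self.segment_len - self.shift


@dataclass(frozen=True)
class ARConfig:
    """Model order and frequency-grid resolution for Burg AR estimation."""

    order: int = 16
    padded_len: int = 1024

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValidationError(f"AR order must be >= 1, got {self.order}")
        if self.padded_len < 2:
            raise ValidationError(f"padded_len must be >= 2, got {self.padded_len}")


@dataclass(frozen=True)
class PSDEstimate:
    """A one-sided PSD on an ascending frequency grid from 0 to fs/2."""

    freqs: np.ndarray           # Hz
    power: np.ndarray           # ms^2/Hz
    method: str                 # "welch" | "ar"
    fs: float
    n_segments_averaged: int | None = None
    config: "WelchConfig | ARConfig | None" = None

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if freqs.shape != power.shape:
            raise ValidationError("freqs and power must have the same shape")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)

    def total_power(self) -> float:
        """Trapezoidal integral of the density over the whole grid, ms^2."""
        return float(np.trapezoid(self.power, self.freqs))


@dataclass(frozen=True)
class BandPowers:
    """Absolute band powers (ms^2), their ratio and normalised units."""

    tp: float
    vlf: float
    lf: float
    hf: float
    lf_hf: float
    lf_nu: float
    hf_nu: float
    band_edges: tuple[float, float, float, float] = DEFAULT_BAND_EDGES

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "vlf": self.vlf, "lf": self.lf, "hf": self.hf,
            "lf_hf": self.lf_hf, "lf_nu": self.lf_nu, "hf_nu": self.hf_nu,
        }


def welch_psd(series: EvenlySampledSeries, cfg: WelchConfig | None = None) -> PSDEstimate:
    """Welch averaged-periodogram PSD of an evenly resampled tachogram.

    Each of the P = floor((N - D)/S) + 1 segments is mean-removed, windowed,
    zero-padded to ``padded_len`` and transformed; the one-sided densities
    are averaged. The density is scaled by the window power (sum of squared
    coefficients) so that the trapezoidal integral of a single-segment
    rectangular-window estimate equals the segment variance.
    """
    cfg = cfg or WelchConfig()
    n = len(series)
    if n < cfg.segment_len:
        raise InsufficientDataError(
            f"series has {n} samples but one Welch segment needs {cfg.segment_len}"
        )
    freqs, power = sps.welch(
        series.values,
        fs=series.fs,
        window=cfg.scipy_window,
        nperseg=cfg.segment_len,
        noverlap=cfg.noverlap,
        nfft=cfg.padded_len,
        detrend="constant",
        scaling="density",
    )
    n_segments = (n - cfg.segment_len) // cfg.shift + 1
    return PSDEstimate(freqs, power, method="welch", fs=series.fs,
                       n_segments_averaged=n_segments, config=cfg)


def burg_coefficients(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Burg's method: AR coefficients of the monic polynomial and noise power.

    Returns ``(a, sigma2)`` with ``a = [a_1 .. a_p]`` such that the model is
    ``x_t + a_1 x_{t-1} + ... + a_p x_{t-p} = e_t`` (for a process
    ``x_t = phi_1 x_{t-1} + ...`` the returned ``a_k`` equal ``-phi_k``).
    Reflection coefficients minimise the summed forward and backward
    prediction error at each order; ``sigma2`` is the final prediction-error
    power.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if order >= n:
        raise ValidationError(f"AR order {order} must be below the series length {n}")
    a = np.zeros(0)
    sigma2 = float(np.dot(x, x)) / n
    f = x[1:].copy()   # forward prediction error
    b = x[:-1].copy()  # backward prediction error
    for _ in range(order):
        denom = np.dot(f, f) + np.dot(b, b)
        if denom <= 0:
            a = np.concatenate([a, np.zeros(order - a.size)])
            break
        k = -2.0 * np.dot(f, b) / denom
        a = np.concatenate([a, [0.0]]) + k * np.concatenate([a[::-1], [1.0]])
        sigma2 *= 1.0 - k * k
        f, b = f[1:] + k * b[1:], b[:-1] + k * f[:-1]
    return a, sigma2


def burg_psd(series: EvenlySampledSeries, cfg: ARConfig | None = None) -> PSDEstimate:
    """Parametric PSD from a Burg-fitted AR model's frequency response.

    The one-sided density is ``2 sigma^2 / (fs |A(f)|^2)`` on the positive
    grid (DC and Nyquist are not doubled), with ``A(f)`` the monic AR
    polynomial evaluated on the unit circle over ``padded_len`` FFT points.
    A numerically zero-variance input yields a flat zero PSD.
    """
    cfg = cfg or ARConfig()
    x = series.values
    if cfg.order >= len(series):
        raise ValidationError(
            f"AR order {cfg.order} must be below the series length {len(series)}"
        )
    freqs = np.fft.rfftfreq(cfg.padded_len, d=1.0 / series.fs)
    if float(np.var(x)) <= 1e-30:
        return PSDEstimate(freqs, np.zeros_like(freqs), method="ar", fs=series.fs, config=cfg)
    a, sigma2 = burg_coefficients(x, cfg.order)
    denom = np.abs(np.fft.rfft(np.concatenate([[1.0], a]), n=cfg.padded_len)) ** 2
    power = sigma2 / (series.fs * denom)
    power *= 2.0
    power[0] /= 2.0
    if cfg.padded_len % 2 == 0:
        power[-1] /= 2.0
    return PSDEstimate(freqs, power, method="ar", fs=series.fs, config=cfg)


def _band_integral(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral over [lo, hi] with edge values interpolated."""
    if hi <= lo:
        return 0.0
    inside = (freqs > lo) & (freqs < hi)
    f = np.concatenate([[lo], freqs[inside], [hi]])
    p = np.concatenate([
        [np.interp(lo, freqs, power)],
        power[inside],
        [np.interp(hi, freqs, power)],
    ])
    return float(np.trapezoid(p, f))


def band_powers(
    psd: PSDEstimate,
    edges: tuple[float, float, float, float] = DEFAULT_BAND_EDGES,
) -> BandPowers:
    """Integrate a PSD over the VLF/LF/HF bands and derive ratio indices.

    ``edges = (vlf_lo, vlf_hi, lf_hi, hf_hi)`` must be ascending. Because
    the density is interpolated at the exact edges, contiguous bands tile
    [vlf_lo, hf_hi] and TP = VLF + LF + HF. When HF is zero the LF/HF ratio
    is reported as NaN (likewise the normalised units when TP equals VLF).
    """
    vlf_lo, vlf_hi, lf_hi, hf_hi = edges
    if not (vlf_lo < vlf_hi < lf_hi < hf_hi):
        raise ValidationError(f"band edges must be strictly ascending, got {edges}")
    if vlf_lo < 0 or hf_hi > psd.freqs[-1] + 1e-12:
        raise ValidationError(
            f"band edges {edges} must lie within [0, {psd.freqs[-1]}] Hz"
        )
    f, p = psd.freqs, psd.power
    tp = _band_integral(f, p, vlf_lo, hf_hi)
    vlf = _band_integral(f, p, vlf_lo, vlf_hi)
    lf = _band_integral(f, p, vlf_hi, lf_hi)
    hf = _band_integral(f, p, lf_hi, hf_hi)
    lf_hf = lf / hf if hf > 0 else float("nan")
    denom = tp - vlf
    if denom > 0:
        lf_nu = 100.0 * lf / denom
        hf_nu = 100.0 * hf / denom
    else:
        lf_nu = hf_nu = float("nan")
    return BandPowers(tp=tp, vlf=vlf, lf=lf, hf=hf, lf_hf=lf_hf,
                      lf_nu=lf_nu, hf_nu=hf_nu, band_edges=tuple(edges))


def frequency_analysis(
    rri: RRiSeries,
    method: str = "welch",
    fs: float = 4.0,
    detrend_degree: int | None = 1,
    cfg: "WelchConfig | ARConfig | None" = None,
    band_edges: tuple[float, float, float, float] = DEFAULT_BAND_EDGES,
) -> tuple[PSDEstimate, BandPowers]:
    """Full frequency-domain pipeline on a raw tachogram.

    interpolate_resample(fs) -> detrend_polynomial(detrend_degree) ->
    welch_psd | burg_psd -> band_powers. ``detrend_degree=None`` skips
    detrending.
    """
    if method not in ("welch", "ar"):
        raise ValidationError(f"method must be 'welch' or 'ar', got {method!r}")
    even = interpolate_resample(rri, fs=fs)
    if detrend_degree is not None:
        even = detrend_polynomial(even, degree=detrend_degree)
    if method == "welch":
        psd = welch_psd(even, cfg if isinstance(cfg, WelchConfig) else None)
    else:
        psd = burg_psd(even, cfg if isinstance(cfg, ARConfig) else None)
    return psd, band_powers(psd, edges=band_edges)
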