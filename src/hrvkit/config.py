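"""Analysis defaults shared by the CLI, serializable as a flat key=value file."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .errors import ValidationError

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Every adjustable analysis default in one flat record.

    The values are the package defaults: ECG passband 5-200 Hz, 4 Hz
    resampling, Welch 256-sample segments with 128-sample overlap and a Hann
    window, AR order 16, contiguous VLF/LF/HF bands at 0/0.04/0.15/0.4 Hz,
    linear detrending, and 30 s non-overlapping time-varying windows.
    """

    passband_low: float = 5.0
    passband_high: float = 200.0
    resample_fs: float = 4.0
    welch_segment: int = 256
    welch_overlap: int = 128
    welch_window: str = "hann"
    ar_order: int = 16
    band_vlf_lo: float = 0.0
    band_vlf_hi: float = 0.04
    band_lf_hi: float = 0.15
    band_hf_hi: float = 0.4
    detrend_degree: int = 1
    tv_segment_s: float = 30.0
    tv_overlap_s: float = 0.0

    @property
    def band_edges(self) -> tuple[float, float, float, float]:
        return (self.band_vlf_lo, self.band_vlf_hi, self.band_lf_hi, self.band_hf_hi)

    def save(self, path: str | Path) -> None:
        lines = [f"{key}={value}" for key, value in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        known = {f.name: f.type for f in fields(cls)}
        casts = {f.name: type(getattr(cls(), f.name)) for f in fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"{path}: line {lineno} is not key=value: {line!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValidationError(f"{path}: unknown config key {key!r} (line {lineno})")
            try:
                kwargs[key] = casts[key](value.strip())
            except ValueError:
                raise ValidationError(
                    f"{path}: cannot parse {value.strip()!r} as {casts[key].__name__} "
                    f"for key {key!r} (line {lineno})"
                ) from None
        return cls(**kwargs)
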