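"""Readers for plain-text RRi/ECG data and Polar HRM files; CSV result export.

Supported inputs are deliberately text-only: one-value-per-line tachograms
(.txt, ms or s), one-sample-per-line ECG traces, and the INI-style Polar
heart-rate-monitor export (.hrm, ``[HRData]`` section). Vendor binary formats
are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ParseError, ValidationError
from .series import ECGRecord, RRiSeries

__all__ = [
    "read_rri_text",
    "read_polar_hrm",
    "read_ecg_text",
    "ResultsTable",
    "write_results_csv",
]


def _read_numeric_lines(path: str | Path) -> np.ndarray:
    """Parse one float per line; '#' comment lines and blank lines are skipped."""
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise ParseError(f"{path}: non-numeric token {line!r} at line {lineno}") from None
    if not values:
        raise EmptyInputError(f"{path}: no numeric data found")
    return np.asarray(values, dtype=float)


def read_rri_text(path: str | Path, units: str = "ms") -> RRiSeries:
    """Read a plain-text tachogram, one RR interval per line.

    Parameters
    ----------
    path : path
        Text file with one numeric token per line. Blank lines and lines
        starting with ``#`` are skipped.
    units : {"ms", "s"}
        Unit of the stored values; seconds are converted to ms.
    """
    if units not in ("ms", "s"):
        raise ValidationError(f"units must be 'ms' or 's', got {units!r}")
    values = _read_numeric_lines(path)
    if units == "s":
        values = values * 1000.0
    if np.any(values <= 0):
        bad = int(np.argmax(values <= 0))
        raise ValidationError(f"{path}: non-positive RR interval {values[bad]!r} (entry {bad + 1})")
    return RRiSeries(values, label=str(path))


def read_polar_hrm(path: str | Path) -> RRiSeries:
    """Read RR intervals from a Polar .hrm heart-rate-monitor file.

    The file is INI-style text; RR intervals in ms are listed one per line in
    the ``[HRData]`` section. In multi-column exports the RR interval is the
    first whitespace-separated field of each line. ``[Params]`` metadata, if
    present, is kept as the series label.
    """
    section = None
    values: list[float] = []
    params: list[str] = []
    found_hrdata = False
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1].strip().lower()
                if section == "hrdata":
                    found_hrdata = True
                continue
            if section == "params":
                params.append(line)
            elif section == "hrdata":
                token = line.split()[0]
                try:
                    values.append(float(token))
                except ValueError:
                    raise ParseError(f"{path}: non-numeric RR value {token!r} at line {lineno}") from None
    if not found_hrdata:
        raise FormatError(f"{path}: no [HRData] section found; not a Polar HRM file?")
    if not values:
        raise EmptyInputError(f"{path}: [HRData] section is empty")
    label = f"{path}" + (f" ({'; '.join(params)})" if params else "")
    return RRiSeries(np.asarray(values), label=label)


def read_ecg_text(path: str | Path, fs: float) -> ECGRecord:
    """Read a plain-text ECG trace (one voltage sample per line) at ``fs`` Hz."""
    if not fs > 0:
        raise ValidationError(f"sampling frequency must be > 0, got {fs!r}")
    samples = _read_numeric_lines(path)
    return ECGRecord(samples, fs=fs)


@dataclass
class ResultsTable:
    """Ordered per-segment analysis results destined for CSV export.

    Each row covers one analysis segment ``[segment_start_s, segment_end_s]``;
    stationary analyses produce a single row spanning the whole record.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.frame, pd.DataFrame):
            self.frame = pd.DataFrame(self.frame)
        cols = list(self.frame.columns)
        if len(cols) != len(set(cols)):
            raise ValidationError("ResultsTable column names must be unique")
        for required in ("segment_start_s", "segment_end_s"):
            if required not in cols:
                raise ValidationError(f"ResultsTable requires a {required!r} column")

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "ResultsTable":
        return cls(pd.DataFrame.from_records(list(records)))

    def __len__(self) -> int:
        return len(self.frame)


def write_results_csv(table: ResultsTable, path: str | Path) -> None:
    """Write a :class:`ResultsTable` as RFC-4180-style CSV.

    Floats are rendered with enough digits that reading the file back
    reproduces every value to better than 1e-6 relative.
    """
    if isinstance(table, pd.DataFrame):
        table = ResultsTable(table)
    if len(table) == 0:
        raise ValidationError("refusing to write an empty results table")
    try:
        table.frame.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
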