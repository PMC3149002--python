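"""Time-series container and delimited-text I/O.

A trace is a pair of equal-length vectors: sampling times (strictly
increasing, in whatever unit the instrument reports — seconds for calcium
imaging, hours for circadian RNA courses) and signal values (arbitrary
units, e.g. a fluorescence ratio or a normalised expression level).
Uniform sampling is never assumed; all downstream analysis works on the
raw time stamps.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "TimeSeriesValidationError",
    "read_timeseries",
    "write_timeseries",
    "write_result_table",
    "write_posterior_csv",
]


class TimeSeriesValidationError(ValueError):
    """Raised when a trace violates the container invariants."""


@dataclass(frozen=True)
class TimeSeries:
    """A sampled signal d(t_i) at N (possibly non-uniform) time points."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise TimeSeriesValidationError(
                "times and values must be 1-D arrays of equal length"
            )
        if t.size < 3:
            raise TimeSeriesValidationError(
                f"need at least 3 time points, got {t.size}"
            )
        if not (np.isfinite(t).all() and np.isfinite(v).all()):
            raise TimeSeriesValidationError("times and values must be finite")
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise TimeSeriesValidationError(
                f"times must be strictly increasing; violation at index {bad[0] + 1}"
            )

    def __len__(self) -> int:
        return self.times.size

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def window(self, start: int, stop: int, label: str | None = None) -> "TimeSeries":
        """Sub-series over the half-open index range [start, stop)."""
        return TimeSeries(
            self.times[start:stop],
            self.values[start:stop],
            self.label if label is None else label,
        )

    def scaled(self, k: float) -> "TimeSeries":
        return replace(self, values=self.values * k)


def _resolve_column(df: pd.DataFrame, col) -> pd.Series:
    if isinstance(col, int) or (isinstance(col, str) and col not in df.columns):
        try:
            idx = int(col)
        except (TypeError, ValueError):
            raise KeyError(f"column {col!r} not found in {list(df.columns)}")
        return df.iloc[:, idx]
    return df[col]


def read_timeseries(path, time_column=0, value_column=1, label: str | None = None) -> TimeSeries:
    """Read a two-column delimited trace (comma or tab, auto-detected).

    A header row is optional; columns may be addressed by name or by
    0-based index.  Rows with non-numeric entries are rejected with their
    row numbers reported.
    """
    with open(path) as fh:
        text = fh.read()
    first = text.splitlines()[0] if text else ""
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","

    def _first_cell_numeric(line: str) -> bool:
        try:
            float(line.split(sep)[0])
            return True
        except ValueError:
            return False

    header = None if (first and _first_cell_numeric(first)) else 0
    df = pd.read_csv(
        io.StringIO(text), sep=sep, header=header, float_precision="round_trip"
    )
    t_raw = pd.to_numeric(_resolve_column(df, time_column), errors="coerce")
    v_raw = pd.to_numeric(_resolve_column(df, value_column), errors="coerce")
    bad = np.nonzero(t_raw.isna().to_numpy() | v_raw.isna().to_numpy())[0]
    if bad.size:
        raise TimeSeriesValidationError(
            f"non-numeric entries at data rows {bad.tolist()}"
        )
    return TimeSeries(
        t_raw.to_numpy(float),
        v_raw.to_numpy(float),
        label=label if label is not None else str(path),
    )


def write_timeseries(ts: TimeSeries, path) -> None:
    """Write a trace as two-column CSV with full float precision."""
    df = pd.DataFrame({"time": ts.times, "value": ts.values})
    df.to_csv(path, index=False, float_format="%.17g")


RESULT_COLUMNS = ["trace", "method", "period", "sigma", "snr", "logZ"]


def write_result_table(results, path) -> None:
    """Write per-trace summaries as a CSV table.

    Each summary is a mapping with keys trace, method, period, sigma and
    optionally snr and logZ; an empty collection yields a header-only file.
    """
    rows = [{k: r.get(k, "") for k in RESULT_COLUMNS} for r in results]
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, index=False)


def write_posterior_csv(omega: np.ndarray, density: np.ndarray, path) -> None:
    """Export a posterior curve as two-column CSV (omega, probability)."""
    pd.DataFrame({"omega": omega, "probability": density}).to_csv(
        path, index=False, float_format="%.17g"
    )
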