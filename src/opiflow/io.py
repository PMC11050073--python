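"""Reading and writing quarterly death series as CSV.

The on-disk schema mirrors the cadence of national surveillance releases:
two columns, ``period`` (``YYYYQn``) and ``deaths``. Lines starting with
``#`` are comments (the writer records the configuration hash there), so a
written file reads straight back.
"""

from __future__ import annotations

import re
import warnings

import pandas as pd

from .errors import ParseError

_PERIOD_RE = re.compile(r"^(\d{4})Q([1-4])$")


def read_observed_csv(path) -> pd.Series:
    """Read a quarterly death series; returns a Series with a quarterly PeriodIndex.

    The series must be gap-free and duplicate-free; out-of-order rows are
    sorted with a warning.
    """
    df = pd.read_csv(path, comment="#", dtype={"period": str})
    if list(df.columns) != ["period", "deaths"]:
        raise ParseError(
            f"{path}: expected columns ['period', 'deaths'], got {list(df.columns)}"
        )
    periods = []
    for row, label in enumerate(df["period"], start=1):
        match = _PERIOD_RE.match(str(label).strip())
        if not match:
            raise ParseError(f"{path} row {row}: malformed period label {label!r}")
        periods.append(pd.Period(year=int(match[1]), quarter=int(match[2]), freq="Q"))
    deaths = pd.to_numeric(df["deaths"], errors="coerce")
    for row, value in enumerate(deaths, start=1):
        if pd.isna(value) or value < 0:
            raise ParseError(f"{path} row {row}: deaths must be a non-negative number")

    series = pd.Series(deaths.to_numpy(dtype=float), index=pd.PeriodIndex(periods, freq="Q"),
                       name="deaths")
    if series.index.has_duplicates:
        dupes = series.index[series.index.duplicated()].unique()
        raise ParseError(f"{path}: duplicate period(s) {list(map(str, dupes))}")
    if not series.index.is_monotonic_increasing:
        warnings.warn(f"{path}: periods out of order; sorting", stacklevel=2)
        series = series.sort_index()
    expected = pd.period_range(series.index[0], series.index[-1], freq="Q")
    if len(series) != len(expected):
        missing = expected.difference(series.index)
        raise ParseError(f"{path}: gap(s) in series at {list(map(str, missing))}")
    return series


def write_series_csv(series: pd.Series, path, config_hash: str | None = None) -> None:
    """Write a quarterly series as ``period,deaths`` CSV (deaths to 2 decimals)."""
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_sha256={config_hash}\n")
        fh.write("period,deaths\n")
        for period, value in series.items():
            fh.write(f"{period},{value:.2f}\n")
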