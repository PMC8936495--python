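"""Readers and writers for station-level monitoring tables.

The canonical interchange format is long CSV/TSV: one row per station-year with
columns ``station_id, lat, lon, year`` followed by one numeric column per
measured variable. A thin adapter ingests/emits the spreadsheet layout common
in monitoring archives (one sheet per survey year). Every CSV the pipeline
writes starts with a ``# columns: ...`` schema comment line.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .fisher import DataError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["station_id", "lat", "lon", "year"]

__all__ = [
    "REQUIRED_COLUMNS",
    "read_dataset",
    "write_dataset",
    "read_excel_yearly",
    "write_excel_yearly",
    "read_stations",
    "matrix_for_year",
    "write_csv_with_schema",
    "read_csv_with_schema",
]


def _validate_long(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{source}: missing required column(s) {missing}")
    df = df.copy()
    df["station_id"] = df["station_id"].astype(str)
    variables = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    for col in ["lat", "lon", "year", *variables]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"{source}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}, row {row}"
            )
        df[col] = coerced
    df["year"] = df["year"].astype(int)
    dup = df.duplicated(subset=["station_id", "year"])
    if dup.any():
        pairs = df.loc[dup, ["station_id", "year"]].iloc[0]
        raise DataError(
            f"{source}: duplicate station-year row "
            f"({pairs['station_id']}, {pairs['year']})"
        )
    return df


def read_dataset(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a long-format dataset; returns (long table, station table).

    Accepts CSV/TSV (delimiter sniffed from the extension) or an Excel workbook
    with one sheet per year. The station table has one row per station with its
    coordinates (taken from the first year it appears).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = read_excel_yearly(path)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, comment="#")
        df = _validate_long(df, path.name)
    stations = (
        df.drop_duplicates("station_id")[["station_id", "lat", "lon"]]
        .reset_index(drop=True)
    )
    per_year = df.groupby("year")["station_id"].count()
    logger.info(
        "%s: %d rows, %d stations, years %d-%d",
        path.name, len(df), len(stations), per_year.index.min(), per_year.index.max(),
    )
    return df, stations


def write_dataset(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a long-format dataset as CSV with a schema comment header."""
    return write_csv_with_schema(df, path)


def read_excel_yearly(path: str | Path) -> pd.DataFrame:
    """Read a workbook with one sheet per survey year into one long table.

    Sheet names must parse as integer years; each sheet needs station_id, lat,
    lon and the variable columns (a ``year`` column is added from the sheet
    name when absent).
    """
    path = Path(path)
    sheets = pd.read_excel(path, sheet_name=None)
    frames = []
    for name, sheet in sheets.items():
        try:
            year = int(str(name).strip())
        except ValueError as exc:
            raise DataError(f"{path.name}: sheet {name!r} is not a year") from exc
        sheet = sheet.copy()
        if "year" not in sheet.columns:
            sheet.insert(3, "year", year)
        frames.append(sheet)
    return _validate_long(pd.concat(frames, ignore_index=True), path.name)


def write_excel_yearly(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a long table as a workbook with one sheet per year."""
    path = Path(path)
    df = _validate_long(df, "in-memory table")
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        for year, grp in df.groupby("year"):
            grp.drop(columns="year").to_excel(xl, sheet_name=str(year), index=False)
    return path


def read_stations(path: str | Path) -> pd.DataFrame:
    """Read a station table (station_id, lat, lon, optional region)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("station_id", "lat", "lon") if c not in df.columns]
    if missing:
        raise DataError(f"{path.name}: missing required column(s) {missing}")
    df["station_id"] = df["station_id"].astype(str)
    return df


def matrix_for_year(
    df: pd.DataFrame, year: int, order: list[str]
) -> pd.DataFrame:
    """Extract one year's observation matrix in the given spatial order.

    Rows with any missing variable are dropped listwise (the count is logged);
    the result is indexed by station id, rows following ``order``, columns the
    measured variables only.
    """
    variables = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    sub = df.loc[df["year"] == int(year)].set_index("station_id")[variables]
    present = [s for s in order if s in sub.index]
    sub = sub.loc[present]
    complete = sub.dropna()
    dropped = len(sub) - len(complete)
    if dropped:
        logger.warning("year %s: dropped %d incomplete station row(s)", year, dropped)
    return complete


def write_csv_with_schema(df: pd.DataFrame, path: str | Path, **to_csv_kwargs) -> Path:
    """Write a CSV whose first line is a ``# columns: ...`` schema comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write("# columns: " + ",".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, index=False, **to_csv_kwargs)
    return path


def read_csv_with_schema(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_csv_with_schema`."""
    return pd.read_csv(path, comment="#")
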